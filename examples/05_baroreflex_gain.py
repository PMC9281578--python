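"""Recover a known baroreflex gain with the transfer-function method.

An LF pressure oscillation drives RR with a configured ms/mmHg gain and a
1-s delay; the cross-spectral estimator recovers the gain (the modulus
discards the delay phase) and the LF coherency quantifies the coupling.
"""

from hrvdcan import BaroCouplingConfig, brs_from_beats, generate_coupled_sbp_rr

for noise_sd in (0.0, 40.0):
    cfg = BaroCouplingConfig(gain=10.0, delay_s=1.0, rr_noise_sd=noise_sd,
                             seed=1)
    sbp, nn = generate_coupled_sbp_rr(cfg, duration_s=960.0)
    res = brs_from_beats(nn, sbp)
    print(f"RR noise SD {noise_sd:5.1f} ms -> BRS {res.brs:6.2f} ms/mmHg, "
          f"LF coherency {res.lf_coherency:.3f} ({res.n_segments} segments)")
print()
print("True gain is 10 ms/mmHg.  Noise leaves the gain nearly unbiased but "
      "lowers the coherency, exactly as in real recordings.")
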