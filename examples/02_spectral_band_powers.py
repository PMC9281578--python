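"""Recover configured band powers with the Welch estimator.

The generator's contract is that the power it is asked for is the power
the packaged estimator measures: 5 Hz resampling, 120-s Hann windows at
50% overlap, trapezoidal band integration.
"""

from hrvdcan import RRModelConfig, generate_rr, nn_band_powers

cfg = RRModelConfig(duration_s=960, mean_nn=900, vlf_power=1500,
                    lf_power=1200, hf_power=1000, seed=5)
bp = nn_band_powers(generate_rr(cfg))

print("band     configured   measured (ms^2)")
print(f"VLF        1500       {bp.vlf:8.1f}")
print(f"LF         1200       {bp.lf:8.1f}")
print(f"HF         1000       {bp.hf:8.1f}")
print(f"TOT_P         -       {bp.tot_p:8.1f}")
print(f"LF/HF         -       {bp.lf_hf:8.2f}")
print()
print("Measured powers match the configured oscillator powers within a few "
      "percent; TOT_P approximates their sum.")
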