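"""Closed loop: synthetic ECG -> R-peak detection -> ECG-derived respiration.

The ECG generator modulates QRS amplitude at the breathing frequency; the
detector recovers every beat with sub-millisecond timing and the EDR
operation reads the breathing rate back off the amplitude series.
"""

import numpy as np

from hrvdcan import detect_r_peaks, edr, generate_ecg

true_resp_hz = 0.25  # 15 breaths/min
beat_times = np.arange(600.0)  # 10 min at 60 bpm
ecg = generate_ecg(beat_times, resp_freq=true_resp_hz, resp_mod_depth=0.2,
                   fs=500)
beats = detect_r_peaks(ecg)
breathing = edr(beats)

timing_err_ms = 1000 * np.abs(beats.r_times - beat_times).max()
print(f"beats generated/detected : {beat_times.size}/{len(beats)}")
print(f"max timing error         : {timing_err_ms:.3f} ms")
print(f"true breathing rate      : {true_resp_hz:.3f} Hz")
print(f"EDR estimate             : {breathing:.3f} Hz")
print()
print("The EDR estimate comes solely from the respiratory amplitude "
      "modulation of the detected QRS complexes.")
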