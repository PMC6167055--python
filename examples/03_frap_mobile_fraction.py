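"""Estimate a FRAP mobile fraction with acquisition-bleaching correction.

Simulates a post-bleach recovery trace in which both the bleached and the
reference region fade by 0.5% per acquired frame, corrects the trace with
the reference, normalizes to the pre-bleach level and fits a single
exponential.
"""

from guvkit.frap import FrapTrace, analyze_trace, correct_and_normalize
from guvkit.synthetic import FrapTruth, simulate_frap

truth = FrapTruth(mobile_fraction=0.10, recovery_tau_s=5.0,
                  acq_bleach_rate=0.005, n_frames=60, frame_interval_s=0.5,
                  noise_sd=20.0, seed=9)
df = simulate_frap(truth)
trace = FrapTrace(df["time_s"].to_numpy(), df["bleached"].to_numpy(),
                  df["reference"].to_numpy(), prebleach=truth.prebleach_level)

curve = correct_and_normalize(trace)
result = analyze_trace(trace)

print(f"ground-truth mobile fraction : {truth.mobile_fraction:.2f}")
print(f"fitted mobile fraction       : {result['mobile_fraction']:.3f}")
print(f"fitted recovery time tau     : {result['tau_s']:.1f} s")
print(f"corrected recovery at t_end  : {curve[-1]:.3f}")
print()
print("A mobile fraction near 0.1 means ~90% of the fluorescent protein in")
print("the bleached zone is immobile — the signature of a stable tethered")
print("contact rather than freely diffusing membrane-bound protein.")
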