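"""Localized CNV calling on a simulated paired tumor/control sample.

Simulates a 5,000-window chromosome at mean depth 100 with one 2x gain and
one 0.5x loss region, calls per-window CNVs with the Geary-Hinkley caller,
and prints how many windows of each state were found and where.
"""

from aluscancnv import LocalizedCallConfig, SimulationTruth, call_localized, simulate_pair
from aluscancnv.simulate import synthetic_windows

windows = synthetic_windows(5000, seed=1)
truth = SimulationTruth(
    cnv_regions=[(1000, 1060, 2.0), (3000, 3060, 0.5)],
    seed=1,
    coverage_fraction=1.0,
)
test, control = simulate_pair(windows, truth)

result = call_localized(test, control, LocalizedCallConfig(alpha=0.05))
calls = result.calls

print(f"analyzed windows : {len(calls)}")
print(f"lambda_t / lambda_c : {result.lambda_t:.1f} / {result.lambda_c:.1f}")
for state in ("gain", "loss", "neutral"):
    print(f"{state:>8}: {(calls['state'] == state).sum()} windows")

gain_hits = (calls.iloc[1000:1060]["state"] == "gain").sum()
loss_hits = (calls.iloc[3000:3060]["state"] == "loss").sum()
print(f"injected 2x gain region  (windows 1000..1059): {gain_hits}/60 called gain")
print(f"injected 0.5x loss region (windows 3000..3059): {loss_hits}/60 called loss")
# The counts show the injected regions are recovered almost completely while
# the background stays near the 5% false-call rate implied by alpha = 0.05.
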