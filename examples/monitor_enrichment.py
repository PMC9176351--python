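"""Watch a strategy change appear in the windowed enrichment ratio.

Builds a synthetic generation stream in which 1,4-quinones occur at the
training-set rate (2%) for the first 1,000 molecules and then jump to
20% — the kind of shift a reward-driven generator shows when it
discovers a useful chromophore — and monitors the windowed enrichment
P_E = P_f / P_tf. P_E should sit near 1 before the step and near 10
after it.
"""

from cfgmon import (
    TrendSpec,
    annotate_stream,
    default_catalog,
    enrichment_trajectory,
    make_stream,
    make_training_set,
    step_trend,
    training_profile,
)

catalog = default_catalog()

training = annotate_stream(
    make_training_set({"1,4-quinone": 0.02}, n=4000, seed=1), catalog
)
profile = training_profile(training, catalog)
print(f"training baseline P_tf(1,4-quinone) = {profile.fractions['1,4-quinone']:.4f}")

stream, _ = make_stream(
    [TrendSpec("1,4-quinone", step_trend(0.02, 0.20, 1000))], 2000, seed=2
)
records = annotate_stream(stream, catalog)

traj = enrichment_trajectory(
    records, profile, catalog, window_length=100, stride=200
)
print("window_end  P_f     P_E")
for pt in traj.points:
    print(f"{pt.window_end:>10d}  {pt.p_f['1,4-quinone']:.3f}  {pt.p_e['1,4-quinone']:6.2f}")
print("P_E near 1 before the step at index 1000, near 10 after it.")
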