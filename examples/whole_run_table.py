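"""Run-level enrichment summary: one P_E per monitored group.

Builds a training set and a generation stream from the labelled pools
(quinones over-represented in the stream) and prints the whole-run
table: group, P_E, generated %, training %. Groups the stream favours
get P_E > 1; untouched groups sit near 1 or below.
"""

from cfgmon import (
    TrendSpec,
    annotate_stream,
    constant_trend,
    default_catalog,
    make_stream,
    make_training_set,
    training_profile,
    whole_run_summary,
)

catalog = default_catalog()
training = annotate_stream(
    make_training_set(
        {"ketone": 0.3, "aniline": 0.1, "1,4-quinone": 0.01, "azo": 0.02},
        n=5000,
        seed=10,
    ),
    catalog,
)
profile = training_profile(training, catalog)

stream, _ = make_stream(
    [
        TrendSpec("1,4-quinone", constant_trend(0.15)),
        TrendSpec("ketone", constant_trend(0.20)),
        TrendSpec("aniline", constant_trend(0.05)),
    ],
    2000,
    seed=11,
)
records = annotate_stream(stream, catalog)

summary = whole_run_summary(records, profile, catalog)
print(summary.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print()
print("P_E > 1 marks groups the stream is enriched in relative to training;")
print("the 15x-boosted 1,4-quinone pool dominates the table.")
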