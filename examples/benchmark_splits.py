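"""Build the benchmark train/validation/test corpora and verify the
structure: 440 documents at 17% ischemia prevalence for training and a
214-document set at 43% split into 115 validation and 99 test (654 total,
a 67/18/15 split)."""

from ischemia_nlp import generate_benchmark_splits

splits = generate_benchmark_splits(seed=7)
total = sum(len(docs) for docs in splits.values())
print(f"total documents: {total}")
for name, docs in splits.items():
    n_pos = sum(d.gold_label for d in docs)
    print(f"{name:>10}: n={len(docs):3d}  positives={n_pos:2d} "
          f"({100 * n_pos / len(docs):.0f}%)  share={100 * len(docs) / total:.0f}%")

# Positive counts are exact (round-half-up of n x prevalence), so the
# printed prevalences are reproduced as equalities, not expectations.
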