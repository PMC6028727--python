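"""Sweep every one of the 560 analysis chains over one dataset and rank
them by PMAD, as a per-dataset league table."""

import warnings

import swathbench as sb

warnings.filterwarnings("ignore")

table, _ = sb.generate_dataset(
    sb.SyntheticTruth(n_proteins=300, group_sizes={"A": 4, "B": 4}, seed=11),
    dataset_id="demo",
)

results = sb.sweep([table], params=sb.ChainParams(impute=sb.ImputeParams(max_iter=30)))
assessments = sb.assess_sweep(results)
ranking = sb.ranking_frame(assessments)

available = ranking[ranking["pmad"].notna()]
failed = ranking[ranking["pmad"].isna()]
print(f"{len(available)} chains assessed, {len(failed)} failed\n")
print("best 10 chains:")
print(available.head(10)[["chain", "pmad", "category", "rank"]].to_string(index=False))
print("\nworst 3 chains:")
print(available.tail(3)[["chain", "pmad", "category", "rank"]].to_string(index=False))

# Rank 1 = smallest PMAD. Chains that could not process the dataset (for
# example a zero-variance column under Z-score) are listed as failed with
# the stage and error class instead of a rank.
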