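"""AMMI stability analysis of yield and the four mineral nutritional yields.

Decomposes each genotype × year mean table into additive main effects and
multiplicative interaction components, exports biplot coordinates, and
ranks genotypes by stability (|PC1| near zero) within performance class.
"""

from pathlib import Path

from nutmet import AnalysisConfig, read_met_table
from nutmet.pipeline import ammi_tables

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    config = AnalysisConfig()
    path = OUT / "trial_plots.csv"
    if not path.exists():
        raise SystemExit("run 01_build_trial_dataset.py first")
    data = read_met_table(path, config)

    results = ammi_tables(data, config)
    for trait, res in results.items():
        res["ranking"].to_csv(OUT / f"ammi_ranking_{trait}.csv")
        res["biplot"].to_csv(OUT / f"ammi_biplot_{trait}.tsv", sep="\t", index=False)
        decomp = res["decomposition"]
        pc1 = decomp.variance_explained[0] if len(decomp.variance_explained) else 0.0
        top = res["ranking"].index[0]
        print(f"{trait}: PC1 explains {pc1:.1f}% of interaction SS; "
              f"most stable above-average genotype: {top}")


if __name__ == "__main__":
    main()
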