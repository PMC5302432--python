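"""Selection indexes over the four mineral nutritional yields.

Scores every genotype with Elston's multiplicative index (lowest
acceptable limits 28/40/50/25 adults·ha⁻¹·year⁻¹ for Fe/Zn/Cu/Mg) and
with the desired-gains index (gains 11/4/0/6 toward 50 adults·ha⁻¹·year⁻¹
for each mineral).
"""

from pathlib import Path

import pandas as pd

from nutmet import AnalysisConfig, read_met_table
from nutmet.pipeline import index_tables

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    config = AnalysisConfig()
    path = OUT / "trial_plots.csv"
    if not path.exists():
        raise SystemExit("run 01_build_trial_dataset.py first")
    data = read_met_table(path, config)

    emi, bdgi, G = index_tables(data, config)
    table = pd.DataFrame({
        "EMI": emi.scores.round(1), "EMI_rank": emi.ranks,
        "EMI_failed_a_limit": emi.flagged,
        "BDGI": bdgi.scores.round(2), "BDGI_rank": bdgi.ranks,
    })
    table.to_csv(OUT / "selection_indexes.csv")
    G.round(3).to_csv(OUT / "genotypic_covariance.csv")
    print("EMI top 3:", ", ".join(emi.ranks.sort_values().index[:3]))
    print("EMI-flagged genotypes (below a limit):",
          ", ".join(emi.flagged[emi.flagged].index) or "none")
    print("BDGI top 3:", ", ".join(bdgi.ranks.sort_values().index[:3]))
    print("BDGI coefficients:",
          {k: round(v, 3) for k, v in bdgi.coefficients.items()})


if __name__ == "__main__":
    main()
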