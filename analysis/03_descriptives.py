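"""Survey-weighted descriptive tables.

Summarises the analysis table the way household-survey reports do:
weighted percentages for categorical variables, weighted mean with SE
for the woman's age, weighted median (Q1, Q3) for the skewed network
measures — per round and pooled — written tidy to
results/descriptives.csv.
"""

from pathlib import Path

import pandas as pd

from hhnet.composition import weighted_descriptives
from hhnet.roster import read_analysis_table

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main():
    analysis = read_analysis_table(ROOT / "scratch" / "analysis.csv")
    desc = weighted_descriptives(analysis)
    desc.to_csv(RESULTS / "descriptives.csv", index=False)
    print(f"wrote {len(desc)} statistics -> {RESULTS / 'descriptives.csv'}")

    med = desc.query("statistic == 'median' and round == 'pooled'")
    print("pooled weighted medians of the network measures:")
    for _, r in med.iterrows():
        print(f"  {r['variable']}: {r['value']:.2f}")
    prev = desc.query("variable == 'outcome_introduced' and level == '1' "
                      "and statistic == 'percent' and round != 'pooled'")
    print("weighted % of infants 6-8 months given solid/semisolid/soft foods:")
    for _, r in prev.iterrows():
        print(f"  {r['round']}: {r['value']:.1f}%")


if __name__ == "__main__":
    main()
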