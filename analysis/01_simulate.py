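"""Generate the synthetic study cohort.

Draws a four-round DHS-like cohort (default 500 households per round,
one eligible 6-8-month-old per household) under the packaged outcome
preset and writes roster.csv / children.csv / truth.json. Raw cohort
files are large and go under scratch/; downstream scripts read them
from there.
"""

from pathlib import Path

from hhnet.simulate import GeneratorConfig, generate_cohort

OUTDIR = Path(__file__).resolve().parent.parent / "scratch" / "cohort"
SEED = 42


def main():
    config = GeneratorConfig(seed=SEED)
    cohort = generate_cohort(config)
    paths = cohort.write(OUTDIR)
    prev = cohort.analysis.groupby("survey_round")["outcome_introduced"].mean()
    print(f"wrote {len(cohort.roster)} roster lines, {len(cohort.children)} children")
    print("per-round outcome prevalence (unweighted):")
    for rnd, p in prev.items():
        print(f"  {rnd}: {100 * p:.1f}%")
    print("files:", *[str(p) for p in paths], sep="\n  ")


if __name__ == "__main__":
    main()
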