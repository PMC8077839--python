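"""Concordance tables for paired specific-vs-generic study results.

Classifies each study in results/inputs/study_results.csv (none / moderate /
strong), aggregates by stratum and generic instrument into a Table-1-style
report, and summarises multi-time-point studies (reclassification of
concordance over time) into a Table-2-style report.
"""

import argparse
from pathlib import Path

from neutralqol import load_study_results
from neutralqol.pipeline import render_concordance_table, render_timecourse_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--studies", type=Path, default=Path("results/inputs/study_results.csv")
    )
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    records = load_study_results(args.studies)
    strata = sorted({r.stratum for r in records})
    gids = sorted({r.generic_id for r in records})
    print(f"{len(records)} study records over strata {strata} vs {gids}")

    levels = render_concordance_table(records, strata, gids)
    print(levels.to_string(index=False))
    levels_path = args.outdir / "concordance_levels.tsv"
    levels.to_csv(levels_path, sep="\t", index=False)

    timecourse = render_timecourse_table(records, strata, gids)
    print(timecourse.to_string(index=False))
    timecourse_path = args.outdir / "concordance_timecourse.tsv"
    timecourse.to_csv(timecourse_path, sep="\t", index=False)
    print(f"wrote {levels_path} and {timecourse_path}")


if __name__ == "__main__":
    main()
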