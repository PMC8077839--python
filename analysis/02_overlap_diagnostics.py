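"""Item-overlap diagnostics: how completely does the generic instrument
cover each specific instrument's items?

Loads the instruments and crosswalks written by 01_generate_inputs.py,
computes construct-level sensitivity (fraction of specific items matched)
and specificity (assumed true-negative mass 0.9 against unmatched generic
items), prints per-stratum ranges, and writes results/diagnostic_table.tsv.
"""

import argparse
from pathlib import Path

from neutralqol import (
    diagnose,
    load_crosswalks,
    load_instrument,
    save_diagnostic_table,
    summarize_ranges,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/inputs"))
    parser.add_argument(
        "--out", type=Path, default=Path("results/diagnostic_table.tsv")
    )
    args = parser.parse_args()

    instruments = {}
    for path in sorted(args.indir.glob("instrument_*")):
        inst = load_instrument(path)
        instruments[inst.instrument_id] = inst

    results = []
    for walk in load_crosswalks(args.indir / "crosswalks.csv"):
        res = diagnose(
            instruments[walk.specific_id], instruments[walk.generic_id], walk
        )
        if hasattr(res, "reason"):
            print(f"{walk.specific_id} vs {walk.generic_id}: excluded ({res.reason})")
        else:
            print(
                f"{res.specific_id} vs {res.generic_id} [{res.stratum}]: "
                f"sensitivity {100 * res.sensitivity:.0f}%, "
                f"specificity {100 * res.specificity:.0f}% "
                f"(tp={res.tp}, fn={res.fn}, fp={res.fp})"
            )
            results.append(res)

    for stratum in sorted({r.stratum for r in results}):
        for gid in sorted({r.generic_id for r in results}):
            rng = summarize_ranges(results, stratum, gid)
            print(
                f"{stratum} vs {gid} (n={rng.n_instruments}): sensitivity "
                f"{100 * rng.sensitivity_min:.0f}-{100 * rng.sensitivity_max:.0f}%, "
                f"specificity "
                f"{100 * rng.specificity_min:.0f}-{100 * rng.specificity_max:.0f}%"
            )

    save_diagnostic_table(results, args.out, sep="\t")
    print(f"wrote {len(results)} comparisons to {args.out}")


if __name__ == "__main__":
    main()
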