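"""Generate the synthetic mini-study every later step consumes.

Writes instrument definitions (a rare-disease and a symptom-specific
questionnaire plus a generic one), their item crosswalks, the derived
diagnostic table, and a paired study-results file under results/inputs/.
Deterministic for a given --seed.
"""

import argparse
from pathlib import Path

from neutralqol import fixture_suite


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument(
        "--outdir", type=Path, default=Path("results/inputs")
    )
    args = parser.parse_args()

    paths = fixture_suite(args.seed, args.outdir)
    print(f"wrote {len(paths)} input files to {args.outdir}:")
    for name, path in paths.items():
        print(f"  {name}: {path.name}")


if __name__ == "__main__":
    main()
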