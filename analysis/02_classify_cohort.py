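#!/usr/bin/env python
"""Classify every allele and assign dose groups.

Reads the synthetic registry from step 01, writes per-patient broad classes
and NSFS dose plus per-allele TM calls under results/classification/, and
reports how the cohort splits by dose.
"""

import argparse
import subprocess
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--registry", type=Path, default=Path("results/synthetic/registry.tsv"))
    parser.add_argument("--domains", type=Path, default=Path("results/synthetic/domains.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/classification"))
    args = parser.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    for sub, extra, name in (
        ("classify", [], "classes.tsv"),
        ("annotate", ["--domains", str(args.domains)], "tm_annotation.tsv"),
    ):
        cmd = [sys.executable, "-m", "wolfram_gp.cli", sub,
               "--registry", str(args.registry), *extra,
               "--out", str(args.out / name)]
        subprocess.run(cmd, check=True)

    import pandas as pd

    classes = pd.read_csv(args.out / "classes.tsv", sep="\t", dtype=str,
                          keep_default_na=False)
    print("NSFS dose distribution among fully genotyped patients:")
    print(classes[classes["nsfs_dose"] != ""]["nsfs_dose"].value_counts().sort_index().to_string())
    n_missing = int((classes["nsfs_dose"] == "").sum())
    print(f"{n_missing} patients lack a usable genotype (missing/unparseable allele)")


if __name__ == "__main__":
    main()
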