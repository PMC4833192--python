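#!/usr/bin/env python
"""Rare-variant filtering of the simulated cohorts.

Applies the MAF<1% frequency filter against the reference sets and the
internal multi-phenotype frequency, excludes samples with more than 30
post-filter variants, assigns consequence classes, and flags potential
compound heterozygotes.  Writes the filtered table and sample lists under
results/filtered/.  Runs 01_simulate_cohort.py outputs; regenerates them
if absent.
"""

import argparse
import os
import subprocess
import sys

from idpanel import FilterConfig, filter_pipeline
from idpanel.io import read_panel, read_samples, read_variant_table, \
    write_variant_table

HERE = os.path.dirname(__file__)
SIM = os.path.join(HERE, "..", "results", "sim")
OUT = os.path.join(HERE, "..", "results", "filtered")


def ensure_sim(seed: int) -> None:
    if not os.path.exists(os.path.join(SIM, "variants.tsv")):
        subprocess.check_call(
            [sys.executable, os.path.join(HERE, "01_simulate_cohort.py"),
             "--seed", str(seed)]
        )


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    ensure_sim(args.seed)

    samples = read_samples(os.path.join(SIM, "samples.tsv"))
    variants = read_variant_table(os.path.join(SIM, "variants.tsv"),
                                  samples=samples)
    read_panel(os.path.join(SIM, "panel.tsv"))

    kept, retained, excluded = filter_pipeline(variants, samples, FilterConfig())
    os.makedirs(OUT, exist_ok=True)
    write_variant_table(kept, os.path.join(OUT, "variants_filtered.tsv"))
    retained.to_csv(os.path.join(OUT, "samples_retained.tsv"), sep="\t",
                    index=False)
    excluded.to_csv(os.path.join(OUT, "samples_excluded.tsv"), sep="\t",
                    index=False)

    print(f"input observations: {len(variants)}; kept after MAF<1%: {len(kept)}")
    print(f"samples retained: {len(retained)} (excluded {len(excluded)} "
          f"with >30 variants)")
    by_class = kept["consequence_class"].value_counts().to_dict()
    print(f"consequence classes: {by_class}")


if __name__ == "__main__":
    main()
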