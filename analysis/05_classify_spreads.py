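#!/usr/bin/env python
"""Karyotype-spread classification: diplochromosome fraction and accuracy.

Classifies synthetic tetraploid metaphase spreads (96% rendered in the
diplochromosome configuration) and measures the classifier's confusion
over all planted classes on noiseless spreads.

Writes results/karyotype.csv.
"""

import sys
from collections import Counter
from pathlib import Path

from sirs_quant.cohorts import diplo_fraction_percent
from sirs_quant.io_core import write_table
from sirs_quant.karyotype import classify_image
from sirs_quant.synthetic import SPREAD_CLASSES, generate_spread

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")


def main():
    OUT.mkdir(exist_ok=True)
    pct, n = diplo_fraction_percent("hs10_metaphase", n=100, seed=SEED)
    print(f"hs10_metaphase: {pct:.1f}% classified diplo-tetraploid (n={n})")

    rows = []
    for planted in SPREAD_CLASSES:
        calls = Counter()
        for seed in range(20):
            image, _ = generate_spread(planted, "female", seed, noise=None)
            call = classify_image(image, "female")
            calls[(call.ploidy_class, call.config_class)] += 1
        (ploidy, config), hits = calls.most_common(1)[0]
        rows.append({"planted_class": planted, "modal_ploidy_call": ploidy,
                     "modal_config_call": config, "modal_fraction": hits / 20})
        print(f"  {planted:26s} -> {ploidy} / {config} ({hits}/20)")
    write_table(rows, OUT / "karyotype.csv")
    print(f"wrote {OUT / 'karyotype.csv'}")


if __name__ == "__main__":
    main()
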