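#!/usr/bin/env python
"""Build the 22-bit, weight-4, distance-4 barcode codebook.

The sum-residue construction (weight-4 words whose on-bit positions sum to 0
mod 22) yields 335 codewords with guaranteed pairwise Hamming distance >= 4 —
enough for 242 genes plus 10 blank barcodes used to monitor false positives.
Writes results/codebook.csv.
"""

from pathlib import Path

import numpy as np

from mopatlas.codebook import build_codebook, pairwise_hamming, write_codebook_csv

OUT = Path("results")


def main() -> None:
    cb = build_codebook(n_bits=22, weight=4, min_distance=4,
                        n_genes=242, n_blanks=10, seed=1)
    d = pairwise_hamming(cb.matrix())
    dmin = int(d[np.triu_indices(len(cb.entries), 1)].min())
    OUT.mkdir(exist_ok=True)
    write_codebook_csv(cb, OUT / "codebook.csv")
    print(f"codebook: {len(cb.gene_names)} genes + {len(cb.blank_names)} blanks "
          f"({len(cb.entries)} codewords), verified min pairwise distance {dmin}")
    print(f"wrote {OUT / 'codebook.csv'}")


if __name__ == "__main__":
    main()
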