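"""Regenerate the bundled data files under src/mtselect/data/.

All three files are deterministic:

* ``rcrs_annotation.tsv`` — the standard rCRS feature coordinate table
  (37 genes, control region, HVS1-3, replication origins).
* ``trna_structure.tsv`` — per-position cloverleaf labels and stem
  pairing for the 22 tRNA genes, from the length-scaled canonical
  template in :mod:`mtselect.genome`.
* ``rcrs_synthetic.fasta`` — a SYNTHETIC 16,569 bp stand-in reference
  sequence (the real rCRS base sequence is not redistributed here). It
  matches the rCRS forward-strand base composition (G-poor light
  strand) and has Watson-Crick complementary tRNA stem pairs so that
  structural-disruption classification behaves realistically. Every
  sequence-dependent computation in the package is reference-agnostic.

Run from the repository root: ``python scripts/build_fixtures.py``
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mtselect.genome import (  # noqa: E402
    RCRS_LENGTH,
    features_from_table,
    trna_structure_from_features,
)

DATA = Path(__file__).resolve().parents[1] / "src" / "mtselect" / "data"

# name, class, start, end, strand_sense (light = rCRS forward), complex
ANNOTATION_ROWS = [
    # control region (wraps the origin of numbering) and hypervariable segments
    ("mtCTR", "control", 16024, 576, "light", "none"),
    ("HVS1", "HVS", 16024, 16383, "light", "none"),
    ("HVS2", "HVS", 57, 372, "light", "none"),
    ("HVS3", "HVS", 438, 574, "light", "none"),
    # replication origins
    ("OriH", "origin", 191, 191, "light", "none"),
    ("OriL", "origin", 5721, 5798, "light", "none"),
    # rRNA
    ("MT-RNR1", "rRNA", 648, 1601, "light", "none"),
    ("MT-RNR2", "rRNA", 1671, 3229, "light", "none"),
    # protein-coding genes with OXPHOS complex membership
    ("MT-ND1", "protein", 3307, 4262, "light", "I"),
    ("MT-ND2", "protein", 4470, 5511, "light", "I"),
    ("MT-CO1", "protein", 5904, 7445, "light", "IV"),
    ("MT-CO2", "protein", 7586, 8269, "light", "IV"),
    ("MT-ATP8", "protein", 8366, 8572, "light", "V"),
    ("MT-ATP6", "protein", 8527, 9207, "light", "V"),
    ("MT-CO3", "protein", 9208, 9990, "light", "IV"),
    ("MT-ND3", "protein", 10059, 10404, "light", "I"),
    ("MT-ND4L", "protein", 10470, 10766, "light", "I"),
    ("MT-ND4", "protein", 10760, 12137, "light", "I"),
    ("MT-ND5", "protein", 12337, 14148, "light", "I"),
    ("MT-ND6", "protein", 14149, 14673, "heavy", "I"),
    ("MT-CYB", "protein", 14747, 15887, "light", "III"),
    # tRNA genes
    ("MT-TF", "tRNA", 577, 647, "light", "none"),
    ("MT-TV", "tRNA", 1602, 1670, "light", "none"),
    ("MT-TL1", "tRNA", 3230, 3304, "light", "none"),
    ("MT-TI", "tRNA", 4263, 4331, "light", "none"),
    ("MT-TQ", "tRNA", 4329, 4400, "heavy", "none"),
    ("MT-TM", "tRNA", 4402, 4469, "light", "none"),
    ("MT-TW", "tRNA", 5512, 5579, "light", "none"),
    ("MT-TA", "tRNA", 5587, 5655, "heavy", "none"),
    ("MT-TN", "tRNA", 5657, 5729, "heavy", "none"),
    ("MT-TC", "tRNA", 5761, 5826, "heavy", "none"),
    ("MT-TY", "tRNA", 5826, 5891, "heavy", "none"),
    ("MT-TS1", "tRNA", 7446, 7514, "heavy", "none"),
    ("MT-TD", "tRNA", 7518, 7585, "light", "none"),
    ("MT-TK", "tRNA", 8295, 8364, "light", "none"),
    ("MT-TG", "tRNA", 9991, 10058, "light", "none"),
    ("MT-TR", "tRNA", 10405, 10469, "light", "none"),
    ("MT-TH", "tRNA", 12138, 12206, "light", "none"),
    ("MT-TS2", "tRNA", 12207, 12265, "light", "none"),
    ("MT-TL2", "tRNA", 12266, 12336, "light", "none"),
    ("MT-TE", "tRNA", 14674, 14742, "heavy", "none"),
    ("MT-TT", "tRNA", 15888, 15953, "light", "none"),
    ("MT-TP", "tRNA", 15956, 16023, "heavy", "none"),
]

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# rCRS forward-strand (light-strand) base composition: G-poor.
BASE_PROBS = {"A": 0.309, "C": 0.313, "G": 0.131, "T": 0.247}
SEQ_SEED = 160424


def build_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        ANNOTATION_ROWS,
        columns=["name", "class", "start", "end", "strand_sense", "complex"],
    )


def build_sequence(structures) -> str:
    rng = np.random.default_rng(SEQ_SEED)
    bases = np.array(list(BASE_PROBS))
    probs = np.array(list(BASE_PROBS.values()))
    probs = probs / probs.sum()
    seq = list(rng.choice(bases, size=RCRS_LENGTH, p=probs))
    # enforce Watson-Crick complementarity across tRNA stem pairs; in genomic
    # space a sense-strand pair is always forward-complementary regardless of
    # the gene's sense strand
    for gene in structures.genes():
        for pos, mate in sorted(structures.partner[gene].items()):
            if pos < mate:
                seq[mate - 1] = COMPLEMENT[seq[pos - 1]]
    return "".join(seq)


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    ann = build_annotation()
    ann.to_csv(DATA / "rcrs_annotation.tsv", sep="\t", index=False)

    features = features_from_table(ann)
    structures = trna_structure_from_features(features)
    structures.to_frame().to_csv(DATA / "trna_structure.tsv", sep="\t", index=False)

    seq = build_sequence(structures)
    with open(DATA / "rcrs_synthetic.fasta", "w") as fh:
        fh.write(
            ">chrM_synthetic synthetic rCRS-like stand-in reference "
            "(rCRS coordinates; composition-matched random sequence)\n"
        )
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    print(f"wrote fixtures to {DATA}")


if __name__ == "__main__":
    main()
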