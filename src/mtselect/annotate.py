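"""Annotation of somatic mtDNA substitutions.

Four orthogonal labels are attached to every catalog mutation:

* **Strand-resolved substitution class.** mtDNA mutagenesis is strongly
  strand-asymmetric; transitions are named by the strand carrying the
  mutated pyrimidine. Under the convention that the rCRS forward
  sequence is the light (L) strand (it is guanine-poor; the heavy
  strand is G-rich), a forward G>A change is a heavy-strand C>T
  (C_H>T_H), forward C>T is C_L>T_L, forward A>G is T_H>C_H, forward
  T>C is T_L>C_L, and every transversion is "other".
* **Functional-region category** (D-loop, Com I/III/IV/V, rRNA, tRNA,
  other) with control-region/HVS membership recorded separately.
* **Protein coding effect** (synonymous / nonsynonymous / stopgain)
  under the vertebrate mitochondrial genetic code (translation table 2:
  TGA=Trp, ATA=Met, AGA/AGG=stop). Genes whose sense is the reverse
  strand (MT-ND6 and eight tRNAs) are complemented before codon
  extraction. Incomplete terminal codons (completed in vivo by
  polyadenylation) are unclassifiable from DNA and are counted as
  nonsynonymous with an "uncertain" flag.
* **tRNA structural element and a Kondrashov-style deleteriousness
  proxy**: a stem substitution that disrupts a Watson-Crick pair with
  its partner base is deleterious; loop/variable substitutions are
  benign by default (G:U wobble counts as non-Watson-Crick unless
  configured otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import MitoGenomeModel, GenomicFeature, STEM_ELEMENTS

STRAND_CLASSES = ("C_H>T_H", "C_L>T_L", "T_H>C_H", "T_L>C_L", "other")

#: forward-strand transition -> strand-resolved class (forward = light strand)
_TRANSITION_CLASS = {
    ("G", "A"): "C_H>T_H",
    ("C", "T"): "C_L>T_L",
    ("A", "G"): "T_H>C_H",
    ("T", "C"): "T_L>C_L",
}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Vertebrate mitochondrial genetic code (translation table 2).
MITO_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "M", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "W", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "*", "AGG": "*",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def classify_substitution_strand(ref: str, alt: str, forward_is_light: bool = True) -> str:
    """Strand-resolved class of a single-base substitution.

    ``ref``/``alt`` are bases on the rCRS forward sequence. Set
    ``forward_is_light=False`` if your convention labels the forward
    sequence as the heavy strand (this swaps H and L).
    """
    ref, alt = ref.upper(), alt.upper()
    for b in (ref, alt):
        if b not in COMPLEMENT:
            raise ValueError(f"non-ACGT allele {b!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    cls = _TRANSITION_CLASS.get((ref, alt), "other")
    if cls != "other" and not forward_is_light:
        cls = cls.replace("_H", "_x").replace("_L", "_H").replace("_x", "_L")
    return cls


# ---------------------------------------------------------------------------
# coding effect


@dataclass(frozen=True)
class CodingEffectResult:
    effect: str  # synonymous | nonsynonymous | stopgain | noncoding
    gene: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    uncertain: bool = False  # incomplete terminal codon


_SEVERITY = {"noncoding": 0, "synonymous": 1, "nonsynonymous": 2, "stopgain": 3}


def _codon_at(
    model: MitoGenomeModel, gene: GenomicFeature, position: int
) -> tuple[str, int, bool]:
    """Sense-strand codon containing ``position`` plus the offset within it.

    Returns (codon, offset 0-2, complete). The codon may be shorter than
    3 nt at an incomplete gene terminus.
    """
    iv = gene.intervals[0]
    if gene.sense_strand == "light":
        cds_index = position - iv.start
    else:
        cds_index = iv.end - position
    n = iv.length(model.genome_length)
    codon_idx, offset = divmod(cds_index, 3)
    bases = []
    for k in range(3):
        i = codon_idx * 3 + k
        if i >= n:
            break
        if gene.sense_strand == "light":
            b = model.ref_base(iv.start + i)
        else:
            b = COMPLEMENT[model.ref_base(iv.end - i)]
        bases.append(b)
    return "".join(bases), offset, len(bases) == 3


def annotate_coding_effect(
    position: int, ref: str, alt: str, model: MitoGenomeModel
) -> CodingEffectResult:
    """Coding effect of a substitution; most severe effect across
    overlapping genes (stopgain > nonsynonymous > synonymous)."""
    model.check_position(position)
    ref, alt = ref.upper(), alt.upper()
    if model.ref_base(position) != ref:
        raise ValueError(
            f"ref allele {ref} does not match reference base "
            f"{model.ref_base(position)} at {position}"
        )
    best: CodingEffectResult | None = None
    for gene in model.protein_genes():
        if not gene.contains(position):
            continue
        codon, offset, complete = _codon_at(model, gene, position)
        sense_ref = ref if gene.sense_strand == "light" else COMPLEMENT[ref]
        sense_alt = alt if gene.sense_strand == "light" else COMPLEMENT[alt]
        assert codon[offset] == sense_ref
        if not complete:
            res = CodingEffectResult("nonsynonymous", gene.name, None, None, uncertain=True)
        else:
            mutated = codon[:offset] + sense_alt + codon[offset + 1 :]
            aa_ref = MITO_CODON_TABLE[codon]
            aa_alt = MITO_CODON_TABLE[mutated]
            if aa_alt == aa_ref:
                effect = "synonymous"
            elif aa_alt == "*" and aa_ref != "*":
                effect = "stopgain"
            else:
                effect = "nonsynonymous"
            res = CodingEffectResult(effect, gene.name, aa_ref, aa_alt)
        if best is None or _SEVERITY[res.effect] > _SEVERITY[best.effect]:
            best = res
    return best or CodingEffectResult("noncoding")


# ---------------------------------------------------------------------------
# tRNA structural classification


def annotate_trna(
    position: int,
    ref: str,
    alt: str,
    model: MitoGenomeModel,
    gene: str | None = None,
    wobble_is_pair: bool = False,
    pathogenic_loop_positions: frozenset[int] = frozenset(),
) -> tuple[str | None, str | None]:
    """(structural element, benign/deleterious) for a tRNA substitution.

    Deleterious = a stem substitution that breaks Watson-Crick
    complementarity with its partner base (the structural-disruption
    proxy for the Kondrashov classification). Loop, variable and
    connector substitutions are benign unless listed in
    ``pathogenic_loop_positions``. Returns (None, None) when the
    position is in no tRNA gene; unmapped tRNA positions raise a
    warning and return ("unclassified", None).
    """
    structures = model.trna_structures
    genes = [gene] if gene else [
        g for g in structures.genes() if position in structures.element[g]
    ]
    if not genes:
        res = model.locate(position)
        if any(model.feature(g).feature_class == "tRNA" for g in res.genes):
            import warnings

            warnings.warn(f"tRNA position {position} missing from structure map", stacklevel=2)
            return "unclassified", None
        return None, None
    gene_name = genes[0]
    element, partner = structures.lookup(gene_name, position)
    if element not in STEM_ELEMENTS:
        cls = "deleterious" if position in pathogenic_loop_positions else "benign"
        return element, cls
    assert partner is not None
    feat = model.feature(gene_name)
    # sense-strand bases of the mutated position and its partner
    if feat.sense_strand == "light":
        s_ref, s_alt = ref, alt
        s_mate = model.ref_base(partner)
    else:
        s_ref, s_alt = COMPLEMENT[ref], COMPLEMENT[alt]
        s_mate = COMPLEMENT[model.ref_base(partner)]

    def is_pair(a: str, b: str) -> bool:
        if COMPLEMENT[a] == b:
            return True
        return wobble_is_pair and {a, b} == {"G", "T"}

    if is_pair(s_ref, s_mate) and not is_pair(s_alt, s_mate):
        return element, "deleterious"
    return element, "benign"


# ---------------------------------------------------------------------------
# catalog-level annotation


def annotate_region(position: int, model: MitoGenomeModel) -> dict:
    res = model.locate(position)
    return {
        "region_category": res.display_category,
        "in_ctr": res.in_control_region,
        "hvs": res.hvs or ("non-HVS" if res.in_control_region else None),
        "gene": res.genes[0] if res.genes else None,
    }


def annotate_catalog(catalog, model: MitoGenomeModel | None = None):
    """Fill every annotation column of a :class:`MutationCatalog` in place.

    Adds ``strand_class``, ``region_category``, ``in_ctr``, ``hvs``,
    ``gene``, ``coding_effect``, ``trna_element`` and
    ``deleteriousness`` columns; returns the catalog.
    """
    model = model or MitoGenomeModel.bundled()
    df = catalog.mutations
    if len(df) == 0:
        for c in (
            "strand_class",
            "region_category",
            "in_ctr",
            "hvs",
            "gene",
            "coding_effect",
            "trna_element",
            "deleteriousness",
        ):
            df[c] = pd.Series(dtype=object)
        return catalog

    df["strand_class"] = [
        classify_substitution_strand(r, a) for r, a in zip(df["ref"], df["alt"])
    ]
    pos = df["position"].to_numpy()
    df["region_category"] = model.display_categories(pos)
    in_ctr = model.mask("mtCTR")[pos]
    df["in_ctr"] = in_ctr
    hvs = model._hvs_name[pos]
    hvs[in_ctr & (hvs == None)] = "non-HVS"  # noqa: E711
    df["hvs"] = hvs
    df["gene"] = model._gene_name[pos]

    df["coding_effect"] = "noncoding"
    protein = model.mask("protein")[pos]
    idx = df.index[protein]
    df.loc[idx, "coding_effect"] = [
        annotate_coding_effect(p, r, a, model).effect
        for p, r, a in zip(df.loc[idx, "position"], df.loc[idx, "ref"], df.loc[idx, "alt"])
    ]

    df["trna_element"] = None
    df["deleteriousness"] = None
    in_trna = model.mask("tRNA")[pos]
    idx = df.index[in_trna]
    trna = [
        annotate_trna(p, r, a, model)
        for p, r, a in zip(df.loc[idx, "position"], df.loc[idx, "ref"], df.loc[idx, "alt"])
    ]
    df.loc[idx, "trna_element"] = [t[0] for t in trna]
    df.loc[idx, "deleteriousness"] = [t[1] for t in trna]
    return catalog


def join_external_pathogenicity(catalog, table: pd.DataFrame | str | Path):
    """Left-join a MitImpact-like pathogenicity table keyed by
    (position, ref, alt); unmatched nonsynonymous mutations get
    class "unknown". Duplicate keys in the table are an error."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    required = {"position", "ref", "alt", "pathogenicity"}
    if missing := required - set(table.columns):
        raise ValueError(f"pathogenicity table missing columns {sorted(missing)}")
    dup = table.duplicated(["position", "ref", "alt"])
    if dup.any():
        row = table.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate pathogenicity key {int(row['position'])}:"
            f"{row['ref']}>{row['alt']}"
        )
    df = catalog.mutations.merge(
        table[["position", "ref", "alt", "pathogenicity"]],
        on=["position", "ref", "alt"],
        how="left",
    )
    if "coding_effect" in df.columns:
        unmatched = df["pathogenicity"].isna() & (df["coding_effect"] == "nonsynonymous")
        df.loc[unmatched, "pathogenicity"] = "unknown"
    catalog.mutations = df
    return catalog
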