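"""Circular mitochondrial genome model: rCRS coordinates, features, DssH.

The human mitochondrial genome is a 16,569 bp circle (rCRS numbering,
1-based inclusive). It carries a non-coding control region (mtCTR) of
1,122 bp spanning the origin of numbering (16024-576) and 37 genes: 13
OXPHOS protein subunits, 2 rRNAs and 22 tRNAs. Intervals that cross the
origin of numbering are encoded with ``start > end``.

Replication is asynchronous strand-displacement: the heavy(H)-strand
daughter is primed at OriH and the fork travels in the decreasing-
coordinate direction; when it passes OriL, light-strand synthesis starts
there and travels in the increasing-coordinate direction. While waiting
for the lagging fork, the displaced parental H strand is single-stranded
and hypermutable; the time it spends single-stranded (DssH, in units of
one full-genome traversal) is a positional mutation-rate proxy:

    DssH(x) = t_lag(x) - t_lead(x)
    t_lead(x) = dist_dec(OriH -> x) / L
    t_lag(x)  = [dist_dec(OriH -> OriL_mid) + dist_inc(OriL_mid -> x)] / L

DssH is zero at (and, by convention here, throughout) OriL, rises
linearly along each replication arc, and is undefined inside the control
region, where initiation events are not covered by this gradient model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

RCRS_LENGTH = 16569

#: rCRS repeat-region sites excluded from somatic calling (inclusive bounds).
DEFAULT_BLACKLIST = ((66, 71), (303, 311), (514, 523), (12418, 12425), (16184, 16193))

DISPLAY_CATEGORIES = ("D-loop", "Com I", "Com III", "Com IV", "Com V", "rRNA", "tRNA", "other")


class InvalidCoordinateError(ValueError):
    """A genomic coordinate falls outside 1..genome_length."""


class ConfigurationError(ValueError):
    """The annotation model violates a structural requirement."""


@dataclass(frozen=True)
class CircularInterval:
    """1-based inclusive interval on a circle; start > end means it wraps."""

    start: int
    end: int

    def __post_init__(self) -> None:
        for v in (self.start, self.end):
            if not (1 <= v <= RCRS_LENGTH):
                raise InvalidCoordinateError(f"coordinate {v} outside 1..{RCRS_LENGTH}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int = RCRS_LENGTH) -> int:
        return circular_length(self, genome_length)

    def contains(self, position: int) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    def positions(self, genome_length: int = RCRS_LENGTH) -> Iterator[int]:
        """Walk the interval in 5'->3' (increasing, wrapping) order."""
        pos = self.start
        while True:
            yield pos
            if pos == self.end:
                return
            pos = pos % genome_length + 1


def circular_length(interval: CircularInterval, genome_length: int = RCRS_LENGTH) -> int:
    """Number of positions covered by a (possibly wrapping) circular interval.

    >>> circular_length(CircularInterval(16024, 576))
    1122
    """
    for v in (interval.start, interval.end):
        if not (1 <= v <= genome_length):
            raise InvalidCoordinateError(f"coordinate {v} outside 1..{genome_length}")
    if interval.start <= interval.end:
        return interval.end - interval.start + 1
    return genome_length - interval.start + 1 + interval.end


@dataclass(frozen=True)
class GenomicFeature:
    """One annotated feature; protein features carry an OXPHOS complex."""

    name: str
    feature_class: str  # protein | tRNA | rRNA | control | HVS | origin
    intervals: tuple[CircularInterval, ...]
    complex_membership: str = "none"  # I | III | IV | V | none
    sense_strand: str = "light"  # light = rCRS forward, heavy = reverse

    def __post_init__(self) -> None:
        if self.feature_class == "protein" and self.complex_membership == "none":
            raise ConfigurationError(f"protein gene {self.name} lacks complex membership")

    def contains(self, position: int) -> bool:
        return any(iv.contains(position) for iv in self.intervals)

    def length(self, genome_length: int = RCRS_LENGTH) -> int:
        return sum(iv.length(genome_length) for iv in self.intervals)


# ---------------------------------------------------------------------------
# tRNA cloverleaf structure


STEM_ELEMENTS = frozenset({"acceptor-stem", "D-stem", "anticodon-stem", "T-stem"})
LOOP_ELEMENTS = frozenset({"D-loop", "anticodon-loop", "T-loop", "variable", "connector"})


def build_cloverleaf(length: int) -> list[tuple[str, int | None]]:
    """Canonical cloverleaf layout for a tRNA of the given length.

    Returns, for each sense-strand position 1..length, its structural
    element label and the 1-based partner position for stem positions
    (``None`` for unpaired positions). Layout: acceptor stem 7 bp,
    D stem 4 bp, anticodon stem 5 bp with a 7-nt loop, T stem 5 bp with a
    7-nt loop, plus connectors; residual length is split between the
    D loop and the variable region (mitochondrial tRNAs are 59-75 nt and
    the shortest lack a D arm, which this scaling reproduces).
    """
    fixed = 7 + 2 + 4 + 4 + 1 + 5 + 7 + 5 + 5 + 7 + 5 + 7
    if length < fixed:
        raise ConfigurationError(f"tRNA of {length} nt is shorter than the minimal cloverleaf")
    rem = length - fixed
    d_loop = math.ceil(rem / 2)
    variable = rem - d_loop

    layout: list[tuple[str, int]] = [
        ("acceptor-stem", 7),
        ("connector", 2),
        ("D-stem", 4),
        ("D-loop", d_loop),
        ("D-stem", 4),
        ("connector", 1),
        ("anticodon-stem", 5),
        ("anticodon-loop", 7),
        ("anticodon-stem", 5),
        ("variable", variable),
        ("T-stem", 5),
        ("T-loop", 7),
        ("T-stem", 5),
        ("acceptor-stem", 7),
    ]
    elements: list[str] = []
    for label, n in layout:
        elements.extend([label] * n)
    assert len(elements) == length

    partner: list[int | None] = [None] * length
    blocks: list[tuple[int, int]] = []  # (start index 0-based, length) per layout block
    i = 0
    for _, n in layout:
        blocks.append((i, n))
        i += n
    # stem block pairs within the layout list: (0,13) acceptor, (2,4) D, (6,8) anticodon, (10,12) T
    for a, b in ((0, 13), (2, 4), (6, 8), (10, 12)):
        sa, na = blocks[a]
        sb, nb = blocks[b]
        assert na == nb
        for k in range(na):
            p, q = sa + k, sb + nb - 1 - k
            partner[p] = q + 1
            partner[q] = p + 1
    return list(zip(elements, partner))


@dataclass
class TrnaStructureMap:
    """Per-gene genomic-position -> cloverleaf element, with stem pairing."""

    element: dict[str, dict[int, str]] = field(default_factory=dict)
    partner: dict[str, dict[int, int]] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return sorted(self.element)

    def lookup(self, gene: str, position: int) -> tuple[str, int | None]:
        elem = self.element[gene].get(position)
        if elem is None:
            raise KeyError(f"position {position} not labeled in {gene}")
        return elem, self.partner[gene].get(position)

    def validate(self) -> None:
        for gene, pairs in self.partner.items():
            for pos, mate in pairs.items():
                if pairs.get(mate) != pos:
                    raise ConfigurationError(f"{gene}: pairing not symmetric at {pos}<->{mate}")
                if self.element[gene][pos] not in STEM_ELEMENTS:
                    raise ConfigurationError(f"{gene}: paired position {pos} not in a stem")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.genes():
            for pos in sorted(self.element[gene]):
                rows.append(
                    {
                        "gene": gene,
                        "pos": pos,
                        "element": self.element[gene][pos],
                        "partner": self.partner[gene].get(pos, 0),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrnaStructureMap":
        m = cls()
        for gene, sub in df.groupby("gene"):
            m.element[str(gene)] = dict(zip(sub["pos"].astype(int), sub["element"]))
            m.partner[str(gene)] = {
                int(p): int(q) for p, q in zip(sub["pos"], sub["partner"]) if int(q) > 0
            }
        m.validate()
        return m


def trna_structure_from_features(features: list[GenomicFeature]) -> TrnaStructureMap:
    """Build the cloverleaf structure map for every tRNA feature.

    Sense position i maps to genomic ``start+i-1`` for light(forward)-sense
    genes and ``end-i+1`` for heavy(reverse)-sense genes.
    """
    m = TrnaStructureMap()
    for feat in features:
        if feat.feature_class != "tRNA":
            continue
        iv = feat.intervals[0]
        n = iv.length()
        cloverleaf = build_cloverleaf(n)

        def genomic(i: int) -> int:  # i is 1-based sense index
            return iv.start + i - 1 if feat.sense_strand == "light" else iv.end - i + 1

        m.element[feat.name] = {}
        m.partner[feat.name] = {}
        for i, (elem, mate) in enumerate(cloverleaf, start=1):
            g = genomic(i)
            m.element[feat.name][g] = elem
            if mate is not None:
                m.partner[feat.name][g] = genomic(mate)
    m.validate()
    return m


# ---------------------------------------------------------------------------
# Locate result


@dataclass(frozen=True)
class LocateResult:
    position: int
    features: tuple[str, ...]
    display_category: str
    in_control_region: bool
    hvs: str | None
    blacklisted: bool
    genes: tuple[str, ...]  # protein/tRNA/rRNA gene names containing the position


class MitoGenomeModel:
    """Annotated circular mitochondrial genome with the DssH model.

    Parameters
    ----------
    features
        Full annotation (genes, control region, HVS segments, origins).
    sequence
        Forward-strand (light-strand) base sequence, length 16,569.
    blacklist
        Repeat-region intervals excluded from somatic calling.
    trna_structures
        Cloverleaf map; built from the tRNA features when not given.
    """

    def __init__(
        self,
        features: list[GenomicFeature],
        sequence: str,
        blacklist: tuple[tuple[int, int], ...] = DEFAULT_BLACKLIST,
        trna_structures: TrnaStructureMap | None = None,
        genome_length: int = RCRS_LENGTH,
        orih_position: int | None = None,
        oril_interval: CircularInterval | None = None,
    ) -> None:
        self.genome_length = genome_length
        self.features = list(features)
        if len(sequence) != genome_length:
            raise ConfigurationError(
                f"sequence length {len(sequence)} != genome length {genome_length}"
            )
        self.sequence = sequence.upper()
        self.blacklist = tuple(CircularInterval(a, b) for a, b in blacklist)
        self._by_name = {f.name: f for f in self.features}

        origins = [f for f in self.features if f.feature_class == "origin"]
        orih = next((f for f in origins if "H" in f.name.upper()), None)
        oril = next((f for f in origins if f is not orih), None)
        self.orih_position = orih_position if orih_position is not None else (
            orih.intervals[0].start if orih else 191
        )
        self.oril_interval = oril_interval if oril_interval is not None else (
            oril.intervals[0] if oril else CircularInterval(5721, 5798)
        )
        self.oril_mid = (self.oril_interval.start + self.oril_interval.end) / 2.0

        self.trna_structures = trna_structures or trna_structure_from_features(self.features)
        self._build_arrays()

    # -- construction -------------------------------------------------------

    def _build_arrays(self) -> None:
        L = self.genome_length
        self._mask: dict[str, np.ndarray] = {}

        def mask_of(intervals: list[CircularInterval]) -> np.ndarray:
            m = np.zeros(L + 1, dtype=bool)
            for iv in intervals:
                if iv.wraps:
                    m[iv.start:] = True
                    m[1 : iv.end + 1] = True
                else:
                    m[iv.start : iv.end + 1] = True
            m[0] = False
            return m

        classes = ("protein", "tRNA", "rRNA", "control", "HVS", "origin")
        for cls in classes:
            ivs = [iv for f in self.features if f.feature_class == cls for iv in f.intervals]
            self._mask[cls] = mask_of(ivs)
        for f in self.features:
            self._mask[f.name] = mask_of(list(f.intervals))
        for cx in ("I", "III", "IV", "V"):
            ivs = [
                iv
                for f in self.features
                if f.feature_class == "protein" and f.complex_membership == cx
                for iv in f.intervals
            ]
            self._mask[f"Com {cx}"] = mask_of(ivs)
        self._mask["blacklist"] = mask_of(list(self.blacklist))
        self._mask["genome"] = mask_of([CircularInterval(1, L)])
        self._mask["mtCTR"] = self._mask["control"]
        self._mask["mtCDR"] = self._mask["genome"] & ~self._mask["control"]
        self._mask["non-HVS"] = self._mask["control"] & ~self._mask["HVS"]

        # tRNA structural masks (stem precedence at the few overlap positions)
        stem = np.zeros(L + 1, dtype=bool)
        nonstem = np.zeros(L + 1, dtype=bool)
        for gene, elems in self.trna_structures.element.items():
            for pos, elem in elems.items():
                if elem in STEM_ELEMENTS:
                    stem[pos] = True
                else:
                    nonstem[pos] = True
        self._mask["tRNA-stem"] = stem
        self._mask["tRNA-nonstem"] = nonstem & ~stem

        # display categories with precedence tRNA > rRNA > protein > control
        disp = np.full(L + 1, "other", dtype=object)
        disp[self._mask["control"]] = "D-loop"
        for cx in ("I", "III", "IV", "V"):
            disp[self._mask[f"Com {cx}"]] = f"Com {cx}"
        disp[self._mask["rRNA"]] = "rRNA"
        disp[self._mask["tRNA"]] = "tRNA"
        disp[0] = ""
        self._display = disp

        # per-position HVS segment name and first containing gene (feature order)
        hvs_name = np.full(L + 1, None, dtype=object)
        for f in self.features:
            if f.feature_class == "HVS":
                hvs_name[self._mask[f.name]] = f.name
        self._hvs_name = hvs_name
        gene_name = np.full(L + 1, None, dtype=object)
        for f in self.features:
            if f.feature_class in ("protein", "tRNA", "rRNA"):
                m = self._mask[f.name] & (gene_name == None)  # noqa: E711
                gene_name[m] = f.name
        self._gene_name = gene_name

        # DssH per position (NaN = undefined inside the control region)
        x = np.arange(L + 1, dtype=float)
        t_lead = np.mod(self.orih_position - x, L) / L
        t_lag = (
            np.mod(self.orih_position - self.oril_mid, L) + np.mod(x - self.oril_mid, L)
        ) / L
        dss = t_lag - t_lead
        oril_mask = np.zeros(L + 1, dtype=bool)
        oril_mask[self.oril_interval.start : self.oril_interval.end + 1] = True
        dss[oril_mask] = 0.0
        dss[self._mask["control"]] = np.nan
        dss[0] = np.nan
        self._dss = dss

    @classmethod
    def bundled(cls) -> "MitoGenomeModel":
        """Load the packaged annotation table and synthetic reference sequence."""
        data = resources.files("mtselect.data")
        ann = pd.read_csv(str(data / "rcrs_annotation.tsv"), sep="\t")
        features = features_from_table(ann)
        seq = read_fasta_sequence(str(data / "rcrs_synthetic.fasta"))
        struct = TrnaStructureMap.from_frame(
            pd.read_csv(str(data / "trna_structure.tsv"), sep="\t")
        )
        return cls(features, seq, trna_structures=struct)

    # -- queries ------------------------------------------------------------

    def feature(self, name: str) -> GenomicFeature:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown feature {name!r}") from None

    def mask(self, region: str) -> np.ndarray:
        """Boolean membership array (index = 1-based position) for a region name."""
        try:
            return self._mask[region]
        except KeyError:
            raise KeyError(f"unknown region {region!r}") from None

    def region_length(self, region: str) -> int:
        return int(self.mask(region).sum())

    def check_position(self, position: int) -> None:
        if not (1 <= position <= self.genome_length):
            raise InvalidCoordinateError(
                f"position {position} outside 1..{self.genome_length}"
            )

    def locate(self, position: int) -> LocateResult:
        """All features containing a position, plus its display category."""
        self.check_position(position)
        hits = tuple(f.name for f in self.features if f.contains(position))
        genes = tuple(
            f.name
            for f in self.features
            if f.feature_class in ("protein", "tRNA", "rRNA") and f.contains(position)
        )
        hvs = next(
            (
                f.name
                for f in self.features
                if f.feature_class == "HVS" and f.contains(position)
            ),
            None,
        )
        return LocateResult(
            position=position,
            features=hits,
            display_category=str(self._display[position]),
            in_control_region=bool(self._mask["control"][position]),
            hvs=hvs,
            blacklisted=bool(self._mask["blacklist"][position]),
            genes=genes,
        )

    def display_categories(self, positions: np.ndarray) -> np.ndarray:
        return self._display[np.asarray(positions, dtype=int)]

    def nonhvs_length_fraction(self) -> float:
        """Percentage of control-region length not covered by HVS1-3.

        With the bundled boundaries (mtCTR 16024-576; HVS1 16024-16383,
        HVS2 57-372, HVS3 438-574) this is 100*309/1122 = 27.54%.
        """
        ctr = next(f for f in self.features if f.feature_class == "control")
        ctr_len = ctr.length(self.genome_length)
        hvs_len = 0
        for f in self.features:
            if f.feature_class != "HVS":
                continue
            for iv in f.intervals:
                for pos in iv.positions(self.genome_length):
                    if not ctr.contains(pos):
                        raise ConfigurationError(
                            f"HVS feature {f.name} extends outside the control region"
                        )
                hvs_len += iv.length(self.genome_length)
        return 100.0 * (ctr_len - hvs_len) / ctr_len

    # -- DssH ---------------------------------------------------------------

    def compute_dssh(self, position: int) -> float:
        """DssH at one position; NaN flags control-region (undefined) sites."""
        self.check_position(position)
        return float(self._dss[position])

    def dssh_defined(self, position: int) -> bool:
        return not math.isnan(self.compute_dssh(position))

    def gene_mean_dssh(self, gene: str) -> float:
        """Arithmetic mean of per-position DssH over the gene body."""
        feat = self.feature(gene)
        vals = self._dss[self.mask(gene)]
        if np.isnan(vals).any():
            raise ConfigurationError(f"gene {gene} overlaps the control region; DssH undefined")
        return float(vals.mean())

    def dssh_profile(self) -> pd.DataFrame:
        """Per-position and per-protein-gene DssH, exportable as TSV."""
        per_pos = pd.DataFrame(
            {"position": np.arange(1, self.genome_length + 1), "dss": self._dss[1:]}
        )
        genes = [f.name for f in self.features if f.feature_class == "protein"]
        per_gene = pd.DataFrame(
            {"gene": genes, "mean_dss": [self.gene_mean_dssh(g) for g in genes]}
        )
        return per_pos, per_gene

    def protein_genes(self) -> list[GenomicFeature]:
        return [f for f in self.features if f.feature_class == "protein"]

    def max_dss_bound(self) -> float:
        """Upper bound 2f, f = leading-fork path fraction OriH -> OriL."""
        f = ((self.orih_position - self.oril_mid) % self.genome_length) / self.genome_length
        return 2.0 * f

    def ref_base(self, position: int) -> str:
        self.check_position(position)
        return self.sequence[position - 1]


# ---------------------------------------------------------------------------
# annotation-table parsing


def features_from_table(table: pd.DataFrame) -> list[GenomicFeature]:
    """Build features from the annotation table (one row per interval)."""
    required = {"name", "class", "start", "end", "strand_sense", "complex"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"annotation table missing columns {sorted(missing)}")
    feats: dict[str, dict] = {}
    for row in table.to_dict("records"):
        rec = feats.setdefault(
            str(row["name"]),
            {
                "feature_class": str(row["class"]),
                "intervals": [],
                "complex_membership": str(row["complex"]),
                "sense_strand": str(row["strand_sense"]),
            },
        )
        rec["intervals"].append(CircularInterval(int(row["start"]), int(row["end"])))
    out = []
    for name, rec in feats.items():
        out.append(
            GenomicFeature(
                name=name,
                feature_class=rec["feature_class"],
                intervals=tuple(rec["intervals"]),
                complex_membership=rec["complex_membership"],
                sense_strand=rec["sense_strand"],
            )
        )
    return out


def read_fasta_sequence(path: str | Path) -> str:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()
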