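"""Tumor/normal paired site calls, the somatic filter cascade, catalogs.

A *site call* is one tumor-sample alternative allele observed at one
position, with strand-split tumor read support and the variant allele
frequency (VAF) in the tumor and in the paired adjacent non-tumor
tissue. The somatic filter cascade keeps a call when

* (i)   at least three reads on *each* strand support the alternative
        allele,
* (ii)  total tumor sequencing coverage is >= 100x,
* (iii) the position is outside the repeat-region blacklist
        (66-71, 303-311, 514-523, 12418-12425, 16184-16193), and
* the call is somatic: tumor VAF >= 1% and paired-normal VAF < 0.5%.

Each filter is a pure predicate, so the cascade is idempotent and
order-independent. Calls are held column-wise in a pandas DataFrame;
:class:`SiteCall` is the record-level view. Only single-base
substitutions enter the catalog; indels are parsed and routed to a side
table, since every downstream analysis is substitution-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import MitoGenomeModel

CALL_COLUMNS = [
    "sample_id",
    "position",
    "ref",
    "alt",
    "t_alt_fwd",
    "t_alt_rev",
    "t_depth",
    "t_vaf",
    "n_vaf",
]

#: Somatic-calling thresholds; surfaced as named constants, never buried.
MIN_STRAND_READS = 3
MIN_COVERAGE = 100
MIN_TUMOR_VAF = 0.01
MAX_NORMAL_VAF = 0.005


class FormatError(ValueError):
    """An input record is missing required fields or violates an invariant."""


@dataclass(frozen=True)
class SiteCall:
    """One tumor/normal paired per-site observation."""

    sample_id: str
    position: int
    ref: str
    alt: str
    t_alt_fwd: int
    t_alt_rev: int
    t_depth: int
    t_vaf: float
    n_vaf: float | None = None


@dataclass(frozen=True)
class VcfTagMap:
    """FORMAT tag names carrying the per-sample fields (config-mapped)."""

    depth: str = "DP"
    vaf: str = "AF"
    alt_fwd: str = "SAF"
    alt_rev: str = "SAR"


@dataclass
class MutationCatalog:
    """Filtered somatic substitutions across a cohort.

    ``n_samples`` is the cohort denominator and must include
    mutation-free samples; it is supplied by the caller (or a sample
    manifest), never inferred from the mutated samples alone.
    """

    mutations: pd.DataFrame
    n_samples: int
    indels: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        n_ids = self.mutations["sample_id"].nunique() if len(self.mutations) else 0
        if self.n_samples < n_ids:
            raise ValueError(
                f"n_samples={self.n_samples} < {n_ids} distinct mutated samples"
            )

    def __len__(self) -> int:
        return len(self.mutations)

    @property
    def vafs(self) -> np.ndarray:
        """Heteroplasmy levels (tumor VAFs) of the catalog mutations."""
        return self.mutations["t_vaf"].to_numpy()

    def mean_mutations_per_sample(self) -> float:
        return len(self.mutations) / self.n_samples

    def subset(self, mask: np.ndarray | pd.Series) -> "MutationCatalog":
        return MutationCatalog(
            self.mutations.loc[np.asarray(mask)].reset_index(drop=True),
            self.n_samples,
            self.indels,
        )


# ---------------------------------------------------------------------------
# reading


def _validate_calls(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["position"] = df["position"].astype(int)
    for c in ("t_alt_fwd", "t_alt_rev", "t_depth"):
        df[c] = df[c].astype(int)
    for c in ("t_vaf", "n_vaf"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = df["t_alt_fwd"] + df["t_alt_rev"] > df["t_depth"]
    if bad.any():
        row = df.loc[bad].iloc[0]
        raise FormatError(
            f"strand alt reads exceed depth at {row['sample_id']}:{row['position']} "
            f"({row['t_alt_fwd']}+{row['t_alt_rev']} > {row['t_depth']})"
        )
    for c in ("t_vaf", "n_vaf"):
        vals = df[c].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise FormatError(f"{c} outside [0,1]")
    return df


def read_site_calls(
    path: str | Path,
    format: str = "tsv",
    tags: VcfTagMap | None = None,
    tumor_sample: str | None = None,
    normal_sample: str | None = None,
) -> pd.DataFrame:
    """Read paired tumor/normal site calls from TSV or VCF.

    The TSV dialect is UTF-8, tab-separated, ``.`` for missing, columns
    ``sample, pos, ref, alt, t_alt_fwd, t_alt_rev, t_depth, t_vaf,
    n_vaf``. VCF input must carry per-sample strand-split alternative
    depths; multi-allelic records are split into one call per alt.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", na_values=["."])
        rename = {"sample": "sample_id", "pos": "position"}
        df = df.rename(columns=rename)
        missing = set(CALL_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"TSV {path} missing columns {sorted(missing)}")
        return _validate_calls(df[CALL_COLUMNS])
    if format == "vcf":
        return _read_vcf(path, tags or VcfTagMap(), tumor_sample, normal_sample)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(
    path: str | Path,
    tags: VcfTagMap,
    tumor_sample: str | None,
    normal_sample: str | None,
) -> pd.DataFrame:
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if len(samples) < 2:
        raise FormatError(f"VCF {path} needs tumor and normal sample columns")
    tumor = tumor_sample or samples[0]
    normal = normal_sample or samples[1]
    for tag in (tags.depth, tags.vaf, tags.alt_fwd, tags.alt_rev):
        if tag not in vf.header.formats:
            raise FormatError(f"VCF {path} lacks FORMAT tag {tag}")

    rows = []
    for rec in vf:
        t = rec.samples[tumor]
        n = rec.samples[normal]
        alts = rec.alts or ()

        def per_alt(value, i):
            if isinstance(value, tuple):
                return value[i]
            return value

        for i, alt in enumerate(alts):
            try:
                fwd = per_alt(t[tags.alt_fwd], i)
                rev = per_alt(t[tags.alt_rev], i)
                depth = t[tags.depth]
                tvaf = per_alt(t[tags.vaf], i)
                nvaf = per_alt(n[tags.vaf], i)
            except KeyError as exc:
                raise FormatError(
                    f"record {rec.chrom}:{rec.pos} {rec.ref}>{alt} missing {exc}"
                ) from None
            if fwd is None or rev is None:
                raise FormatError(
                    f"record {rec.chrom}:{rec.pos} {rec.ref}>{alt} lacks strand depths"
                )
            rows.append(
                {
                    "sample_id": tumor,
                    "position": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                    "t_alt_fwd": int(fwd),
                    "t_alt_rev": int(rev),
                    "t_depth": int(depth),
                    "t_vaf": float(tvaf),
                    "n_vaf": float(nvaf) if nvaf is not None else np.nan,
                }
            )
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return _validate_calls(df)


# ---------------------------------------------------------------------------
# filter cascade


def filter_strand_support(calls: pd.DataFrame) -> pd.DataFrame:
    """Keep calls with >= 3 alt reads on each strand."""
    keep = (calls["t_alt_fwd"] >= MIN_STRAND_READS) & (calls["t_alt_rev"] >= MIN_STRAND_READS)
    return calls.loc[keep]


def filter_coverage(calls: pd.DataFrame) -> pd.DataFrame:
    """Keep calls with total tumor coverage >= 100x."""
    return calls.loc[calls["t_depth"] >= MIN_COVERAGE]


def filter_blacklist(calls: pd.DataFrame, model: MitoGenomeModel) -> pd.DataFrame:
    """Drop calls inside any repeat-region blacklist interval (inclusive)."""
    bl = model.mask("blacklist")
    return calls.loc[~bl[calls["position"].to_numpy()]]


def somatic_predicate(calls: pd.DataFrame) -> pd.Series:
    return (calls["t_vaf"] >= MIN_TUMOR_VAF) & (calls["n_vaf"] < MAX_NORMAL_VAF)


def classify_somatic(
    calls: pd.DataFrame,
    n_samples: int,
    model: MitoGenomeModel | None = None,
) -> tuple[MutationCatalog, dict]:
    """Run the full filter cascade and assemble a somatic catalog.

    Returns the catalog plus a QC report with per-filter removal counts
    (which sum, with the kept count, to the input count). Calls with a
    missing normal VAF are rejected and counted separately.
    """
    model = model or MitoGenomeModel.bundled()
    calls = _validate_calls(calls)
    qc: dict = {"input": int(len(calls))}

    is_snv = (calls["ref"].str.len() == 1) & (calls["alt"].str.len() == 1)
    indels = calls.loc[~is_snv].reset_index(drop=True)
    calls = calls.loc[is_snv]
    qc["indel_side_table"] = int(len(indels))

    no_normal = calls["n_vaf"].isna()
    qc["missing_normal_vaf"] = int(no_normal.sum())
    if qc["missing_normal_vaf"]:
        import warnings

        warnings.warn(
            f"{qc['missing_normal_vaf']} calls lack a normal VAF and were rejected",
            stacklevel=2,
        )
    calls = calls.loc[~no_normal]

    stages = [
        ("fail_strand_support", filter_strand_support),
        ("fail_coverage", filter_coverage),
        ("fail_blacklist", lambda c: filter_blacklist(c, model)),
        ("fail_somatic_vaf", lambda c: c.loc[somatic_predicate(c)]),
    ]
    for name, fn in stages:
        kept = fn(calls)
        qc[name] = int(len(calls) - len(kept))
        calls = kept
    qc["kept"] = int(len(calls))

    catalog = MutationCatalog(calls.reset_index(drop=True), n_samples=n_samples, indels=indels)
    return catalog, qc


# ---------------------------------------------------------------------------
# catalog round trip


def write_catalog(catalog: MutationCatalog, path: str | Path, qc: dict | None = None) -> None:
    """Write a deterministic, sorted, round-trippable catalog TSV."""
    path = Path(path)
    df = catalog.mutations.sort_values(
        ["sample_id", "position", "alt"], kind="mergesort"
    ).reset_index(drop=True)
    with open(path, "w", newline="") as fh:
        fh.write("##mtselect_catalog_v1\n")
        fh.write(f"##n_samples={catalog.n_samples}\n")
        fh.write(
            "##filters=strand>=3+3,coverage>=100,blacklist,"
            "tumor_vaf>=0.01,normal_vaf<0.005\n"
        )
        df.to_csv(fh, sep="\t", index=False, na_rep=".", float_format="%.6g")
    if qc is not None:
        with open(path.with_suffix(".qc.json"), "w") as fh:
            json.dump(qc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_catalog(path: str | Path) -> MutationCatalog:
    n_samples = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            if line.startswith("##n_samples="):
                n_samples = int(line.strip().split("=", 1)[1])
    if n_samples is None:
        raise FormatError(f"{path}: missing ##n_samples header")
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["."])
    df = _validate_calls(df) if len(df) else df
    return MutationCatalog(df.reset_index(drop=True), n_samples=n_samples)


def calls_from_records(records: Iterable[SiteCall]) -> pd.DataFrame:
    """Build a call table from record objects (testing convenience)."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "position": r.position,
                "ref": r.ref,
                "alt": r.alt,
                "t_alt_fwd": r.t_alt_fwd,
                "t_alt_rev": r.t_alt_rev,
                "t_depth": r.t_depth,
                "t_vaf": r.t_vaf,
                "n_vaf": np.nan if r.n_vaf is None else r.n_vaf,
            }
            for r in records
        ],
        columns=CALL_COLUMNS,
    )
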