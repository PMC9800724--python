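"""Synthetic tumor/normal mtDNA site-call cohorts with ground truth.

The generator emulates the statistical structure the selection analysis
assumes, so every pipeline stage and every inference is testable
without any sequencing data:

* per-sample mutation counts are Poisson with a configurable mean
  (default 1.4, the cohort-1 average);
* substitution classes follow a configurable strand-resolved spectrum
  dominated by heavy-strand C>T and light-strand T>C transitions;
* C_H>T_H positions are drawn along the replication arc with intensity
  ``a + b * DssH(x)`` (the replication-exposure mutational gradient);
  all other classes are positionally uniform, and the control region is
  treated as its own uniform compartment;
* region-specific selection is injected by thinning: a proposed
  mutation in feature class F survives with probability
  ``selection_multipliers[F]`` (e.g. ``{"Com V": 0.5}`` halves the
  Complex V rate);
* heteroplasmy is Beta-distributed (low-VAF-enriched by default) and
  read support is binomial at a Poisson depth, split evenly between
  strands; paired-normal VAF is small half-normal contamination noise.

Reference and alternative alleles are consistent with the bundled
reference sequence (the ref allele is the genomic base; the position is
drawn among bases that can realize the drawn class). Every emitted call
appears in the truth table; runs are byte-reproducible under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import COMPLEMENT
from .genome import MitoGenomeModel
from .variants import CALL_COLUMNS

#: forward-strand ref base that realizes each strand-resolved class
CLASS_REF = {"C_H>T_H": "G", "C_L>T_L": "C", "T_H>C_H": "A", "T_L>C_L": "T"}
CLASS_ALT = {"C_H>T_H": "A", "C_L>T_L": "T", "T_H>C_H": "G", "T_L>C_L": "C"}

_TRANSVERSIONS = {"A": ("C", "T"), "C": ("A", "G"), "G": ("C", "T"), "T": ("A", "G")}

DEFAULT_SPECTRUM = {
    "C_H>T_H": 0.50,
    "T_L>C_L": 0.25,
    "C_L>T_L": 0.10,
    "T_H>C_H": 0.05,
    "other": 0.10,
}

_MULTIPLIER_ALIASES = {"tRNA-loop": "tRNA-nonstem"}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults follow the cohort-1 scale (432 samples, 1.4 mutations per
    sample, ~5,084x mean depth); the heteroplasmy Beta(0.3, 3) is a
    stated illustrative choice producing the observed low-VAF
    enrichment.
    """

    n_samples: int = 432
    mean_mutations_per_sample: float = 1.4
    spectrum_probs: dict = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    dssh_gradient: tuple[float, float] = (0.1, 1.0)  # intensity a + b * DssH(x)
    selection_multipliers: dict = field(default_factory=dict)
    heteroplasmy_beta: tuple[float, float] = (0.3, 3.0)
    min_heteroplasmy: float = 0.005
    mean_depth: float = 5084.0
    normal_vaf_noise: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.spectrum_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum_probs sum to {total}, not 1")
        if any(m <= 0 for m in self.selection_multipliers.values()):
            raise ValueError("selection multipliers must be > 0")
        a, b = self.dssh_gradient
        if a < 0 or b < 0:
            raise ValueError("gradient rates must be >= 0")


def _multiplier_array(config: SyntheticConfig, model: MitoGenomeModel) -> np.ndarray:
    mult = np.ones(model.genome_length + 1)
    for key, value in sorted(config.selection_multipliers.items()):
        region = _MULTIPLIER_ALIASES.get(key, key)
        mult[model.mask(region)] *= value
    return mult


def generate_cohort(
    config: SyntheticConfig, model: MitoGenomeModel | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cohort; returns (site calls, truth table).

    The site-call table uses the exact dialect ``read_site_calls``
    consumes; the truth table carries the true class, region and
    heteroplasmy of every emitted call.
    """
    config.validate()
    model = model or MitoGenomeModel.bundled()
    rng = np.random.default_rng(config.seed)
    L = model.genome_length

    seq = np.frombuffer(model.sequence.encode(), dtype="S1").astype("U1")
    seq = np.concatenate([[""], seq])  # 1-based
    a, b = config.dssh_gradient
    dss = np.nan_to_num(model._dss, nan=0.0)
    gradient = a + b * dss
    gradient[model.mask("mtCTR")] = 0.0  # C_H>T_H restricted to the replication arc
    mult = _multiplier_array(config, model)
    cap = max(1.0, mult.max())

    counts = rng.poisson(config.mean_mutations_per_sample, config.n_samples)
    sample_ids = np.repeat(
        np.array([f"S{i:04d}" for i in range(config.n_samples)]), counts
    )
    n_total = int(counts.sum())
    class_names = list(config.spectrum_probs)
    probs = np.array([config.spectrum_probs[c] for c in class_names])
    class_idx = rng.choice(len(class_names), size=n_total, p=probs)
    classes = np.array(class_names, dtype=object)[class_idx]

    positions = np.zeros(n_total, dtype=int)
    all_pos = np.arange(1, L + 1)
    for ci, cname in enumerate(class_names):
        sel = class_idx == ci
        n = int(sel.sum())
        if n == 0:
            continue
        if cname == "other":
            cand = all_pos
            w = np.ones(L)
        else:
            cand = all_pos[seq[1:] == CLASS_REF[cname]]
            w = (gradient if cname == "C_H>T_H" else np.ones(L + 1))[cand]
        w = np.asarray(w, float)
        if w.sum() <= 0:
            raise ValueError(f"zero-length eligible region for class {cname}")
        positions[sel] = rng.choice(cand, size=n, p=w / w.sum())

    # selection thinning
    accept = rng.random(n_total) < mult[positions] / cap
    sample_ids, classes, positions = sample_ids[accept], classes[accept], positions[accept]
    n = int(accept.sum())

    refs = seq[positions]
    alts = np.empty(n, dtype=object)
    for cname, alt in CLASS_ALT.items():
        alts[classes == cname] = alt
    other = classes == "other"
    if other.any():
        pick = rng.integers(0, 2, size=int(other.sum()))
        alts[other] = [
            _TRANSVERSIONS[r][k] for r, k in zip(refs[other], pick)
        ]

    alpha, beta = config.heteroplasmy_beta
    vaf = rng.beta(alpha, beta, size=n)
    low = vaf < config.min_heteroplasmy
    while low.any():
        vaf[low] = rng.beta(alpha, beta, size=int(low.sum()))
        low = vaf < config.min_heteroplasmy

    depth = rng.poisson(config.mean_depth, size=n)
    alt_reads = rng.binomial(depth, vaf)
    fwd = rng.binomial(alt_reads, 0.5)
    rev = alt_reads - fwd
    with np.errstate(invalid="ignore", divide="ignore"):
        t_vaf = np.where(depth > 0, alt_reads / np.maximum(depth, 1), 0.0)
    n_vaf = np.minimum(np.abs(rng.normal(0.0, config.normal_vaf_noise, size=n)), 0.999)

    calls = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "position": positions,
            "ref": refs,
            "alt": alts,
            "t_alt_fwd": fwd,
            "t_alt_rev": rev,
            "t_depth": depth,
            "t_vaf": t_vaf,
            "n_vaf": n_vaf,
        }
    )
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "position": positions,
            "ref": refs,
            "alt": alts,
            "class": classes,
            "region": model.display_categories(positions),
            "true_vaf": vaf,
        }
    )
    return calls, truth


# ---------------------------------------------------------------------------
# deterministic writers (exact dialects consumed by the reader)


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls.rename(columns={"sample_id": "sample", "position": "pos"})
    out.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")


def write_truth_tsv(truth: pd.DataFrame, path: str | Path, config: SyntheticConfig) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"##config={asdict(config)!r}\n")
        truth.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_calls_vcf(calls: pd.DataFrame, path: str | Path) -> None:
    """Emit calls as a VCFv4.2 text file with strand-split alt depths.

    FORMAT: DP (depth), AF (allele frequency), SAF/SAR (alt reads on
    the forward/reverse strand). Two sample columns, TUMOR and NORMAL.
    One record per call, sorted by position then sample.
    """
    header = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chrM,length=16569>",
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        '##FORMAT=<ID=SAF,Number=A,Type=Integer,Description="Alt reads, forward strand">',
        '##FORMAT=<ID=SAR,Number=A,Type=Integer,Description="Alt reads, reverse strand">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL",
    ]
    rows = calls.sort_values(["position", "sample_id", "alt"], kind="mergesort")
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(header) + "\n")
        for r in rows.itertuples(index=False):
            tumor = f"{r.t_depth}:{r.t_vaf:.6g}:{r.t_alt_fwd}:{r.t_alt_rev}"
            normal = f"{r.t_depth}:{r.n_vaf:.6g}:0:0"
            fh.write(
                f"chrM\t{r.position}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"DP:AF:SAF:SAR\t{tumor}\t{normal}\n"
            )


# ---------------------------------------------------------------------------
# filter boundary fixtures


def generate_filter_fixtures(model: MitoGenomeModel | None = None) -> pd.DataFrame:
    """Boundary site calls with known pass/fail verdicts for the somatic
    filter cascade (strand 3+3, depth 100, blacklist edges, VAF
    thresholds)."""
    model = model or MitoGenomeModel.bundled()

    def row(pos, fwd, rev, depth, tvaf, nvaf, expected, reason):
        ref = model.ref_base(pos)
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        return {
            "sample": "FX",
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "t_alt_fwd": fwd,
            "t_alt_rev": rev,
            "t_depth": depth,
            "t_vaf": tvaf,
            "n_vaf": nvaf,
            "expected_pass": expected,
            "reason": reason,
        }

    rows = [
        row(1000, 3, 3, 100, 0.010, 0.004, True, "all thresholds at boundary"),
        row(1000, 2, 3, 100, 0.010, 0.004, False, "fwd strand support below 3"),
        row(1000, 3, 2, 100, 0.010, 0.004, False, "rev strand support below 3"),
        row(1000, 10, 2, 100, 0.010, 0.004, False, "one strand below 3"),
        row(1000, 0, 0, 100, 0.010, 0.004, False, "no alt reads"),
        row(1000, 50, 49, 99, 0.010, 0.004, False, "coverage below 100"),
        row(1000, 50, 50, 5084, 0.020, 0.000, True, "typical deep call"),
        row(1000, 3, 3, 100, 0.009, 0.000, False, "tumor VAF below 1%"),
        row(1000, 3, 3, 100, 0.400, 0.005, False, "normal VAF not below 0.5%"),
        row(1000, 3, 3, 100, 0.010, 0.0049, True, "normal VAF just below 0.5%"),
    ]
    blacklist_edges = [66, 71, 303, 311, 514, 523, 12418, 12425, 16184, 16193]
    outside = [65, 72, 302, 312, 513, 524, 12417, 12426, 16183, 16194]
    for pos in blacklist_edges:
        rows.append(row(pos, 10, 10, 1000, 0.02, 0.0, False, f"blacklist edge {pos}"))
    for pos in outside:
        rows.append(row(pos, 10, 10, 1000, 0.02, 0.0, True, f"just outside blacklist {pos}"))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recovery (truth vs report)


def replay_analysis(config: SyntheticConfig, report, model: MitoGenomeModel | None = None) -> dict:
    """Compare injected selection multipliers and gradient slope against
    a :class:`~mtselect.stats.SelectionReport`'s estimates.

    The Complex V multiplier estimate is the normalized-density ratio of
    Complex V to the mean of the other complexes. The tRNA-loop
    multiplier estimate is composition-corrected: raw stem/loop
    densities confound selection with mutational opportunity (stem
    positions are G/C-balanced by pairing while each substitution class
    requires a specific reference base), so observed counts are divided
    by their expected neutral share given the per-class mutable-target
    content of the stem and non-stem partitions. Approximate 95% CIs
    come from Poisson counts on the log scale.
    """
    model = model or MitoGenomeModel.bundled()
    s = report.sections
    out: dict = {}

    norm = s.get("normalized_complex_density")
    if isinstance(norm, pd.DataFrame):
        by = norm.set_index("complex")
        others = [c for c in ("Com I", "Com III", "Com IV") if c in by.index]
        ref_density = by.loc[others, "normalized_density"].mean()
        est = by.loc["Com V", "normalized_density"] / ref_density
        n_v = by.loc["Com V", "n_mutations"]
        n_o = by.loc[others, "n_mutations"].sum()
        if n_v > 0 and n_o > 0:
            se = np.sqrt(1.0 / n_v + 1.0 / n_o)
            ci = (float(est * np.exp(-1.96 * se)), float(est * np.exp(1.96 * se)))
        else:
            ci = (np.nan, np.nan)
        out["complex_v_multiplier"] = {
            "estimate": float(est),
            "ci95": ci,
            "truth": config.selection_multipliers.get("Com V", 1.0),
        }

    trna = s.get("trna_stem_loop", {})
    if "stem_density" in trna:
        n_l, n_s = trna["counts"]["nonstem"], trna["counts"]["stem"]
        # per-class mutable-target counts in each partition
        seq = np.frombuffer(model.sequence.encode(), dtype="S1").astype("U1")
        seq = np.concatenate([[""], seq])
        stem_mask = model.mask("tRNA-stem")
        nonstem_mask = model.mask("tRNA-nonstem")
        cc = trna.get("class_counts", {"stem": {}, "nonstem": {}})
        e_stem = e_nonstem = 0.0
        all_classes = set(cc["stem"]) | set(cc["nonstem"])
        for cname in all_classes:
            n_c = cc["stem"].get(cname, 0) + cc["nonstem"].get(cname, 0)
            if cname in CLASS_REF:
                base = CLASS_REF[cname]
                t_s = int((stem_mask & (seq == base)).sum())
                t_n = int((nonstem_mask & (seq == base)).sum())
            else:
                t_s = int(stem_mask.sum())
                t_n = int(nonstem_mask.sum())
            if t_s + t_n:
                e_stem += n_c * t_s / (t_s + t_n)
                e_nonstem += n_c * t_n / (t_s + t_n)
        if n_l > 0 and n_s > 0 and e_stem > 0 and e_nonstem > 0:
            est = (n_l / e_nonstem) / (n_s / e_stem)
            se = np.sqrt(1.0 / n_l + 1.0 / n_s)
            ci = (float(est * np.exp(-1.96 * se)), float(est * np.exp(1.96 * se)))
        else:
            est, ci = np.nan, (np.nan, np.nan)
        mult = config.selection_multipliers
        truth = mult.get("tRNA-loop", mult.get("tRNA-nonstem", 1.0)) / mult.get(
            "tRNA-stem", 1.0
        )
        out["trna_loop_multiplier"] = {"estimate": float(est), "ci95": ci, "truth": truth}

    reg = s.get("dssh_regression", {})
    if "slope" in reg:
        out["gradient"] = {
            "slope": reg["slope"],
            "slope_positive": reg["slope"] > 0,
            "truth_b": config.dssh_gradient[1],
            "r": reg["r"],
        }
    return out
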