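"""Selection statistics for somatic mtDNA mutation catalogs.

The central quantity is the **mutation density** of a region: the mean
number of mutations per sample divided by the region length in kb,

    density = (n_mutations / n_samples) / (length_bp / 1000).

Because the positional mutation *rate* along the molecule is itself
non-uniform (heavy-strand C>T mutagenesis tracks DssH, the time the
parental heavy strand spends single-stranded during replication), raw
density differences between regions confound mutation supply with
selection. Three complementary analyses disentangle them:

* a goodness-of-fit of control-region mutations against the neutral
  length expectation for the hypervariable (HVS) vs non-HVS split
  (relaxed selection leaves the observed non-HVS share at its length
  fraction, 27.54% with the bundled boundaries);
* an ordinary least-squares regression of gene-specific C_H>T_H density
  on gene-mean DssH, from which each OXPHOS complex gets a
  *standardization score* (fitted density at its length-weighted mean
  DssH relative to Complex IV); normalized density = observed density /
  score, so residual differences between complexes reflect selection,
  not replication exposure;
* stem vs loop density and Watson-Crick-disruption proportions inside
  the tRNA genes.

All p-values are two-tailed and reported raw (the conventional 0.05
level; a Benjamini-Hochberg option is available for users who test
many regions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotate import STRAND_CLASSES
from .genome import MitoGenomeModel
from .variants import MutationCatalog

DEFAULT_VAF_BINS = (0.01, 0.05, 0.5, 1.0)


@dataclass(frozen=True)
class RegionDensity:
    region: str
    length_bp: int
    n_mutations: int
    n_samples: int

    @property
    def density(self) -> float:
        """Mutations per sample per kb."""
        return (self.n_mutations / self.n_samples) / (self.length_bp / 1000.0)


def mutation_density(
    catalog: MutationCatalog, region: str, model: MitoGenomeModel
) -> RegionDensity:
    """Density of catalog mutations inside a named region.

    ``region`` is any name the genome model resolves: ``genome``,
    ``mtCTR``, ``mtCDR``, ``HVS``, ``non-HVS``, ``rRNA``, ``tRNA``,
    ``Com I``..``Com V``, a gene name, ``tRNA-stem``/``tRNA-nonstem``.
    """
    if catalog.n_samples <= 0:
        raise ValueError("n_samples must be positive")
    mask = model.mask(region)
    length = int(mask.sum())
    n = int(mask[catalog.mutations["position"].to_numpy()].sum()) if len(catalog) else 0
    return RegionDensity(region, length, n, catalog.n_samples)


def spectrum_proportions(catalog: MutationCatalog, region: str, model: MitoGenomeModel):
    """Counts and proportions over strand-substitution classes in a region.

    Proportion = class count / total regional mutations; the table is
    all-zero with NaN proportions when the region holds no mutations.
    """
    df = catalog.mutations
    mask = model.mask(region)
    sub = df.loc[mask[df["position"].to_numpy()]] if len(df) else df
    counts = sub["strand_class"].value_counts().reindex(STRAND_CLASSES, fill_value=0)
    total = int(counts.sum())
    props = counts / total if total else counts.astype(float) * np.nan
    return pd.DataFrame({"count": counts.astype(int), "proportion": props})


def compare_spectra(
    catalog: MutationCatalog, region_a: str, region_b: str, model: MitoGenomeModel
) -> dict:
    """Chi-square comparison of two regions' substitution-class counts."""
    a = spectrum_proportions(catalog, region_a, model)["count"]
    b = spectrum_proportions(catalog, region_b, model)["count"]
    table = np.vstack([a.to_numpy(), b.to_numpy()])
    keep = table.sum(axis=0) > 0
    chi2, p, dof, _ = sps.chi2_contingency(table[:, keep])
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof)}


def compare_heteroplasmy(
    vafs_a: Sequence[float], vafs_b: Sequence[float], test: str = "ks"
) -> tuple[float, float]:
    """Two-tailed KS or Mann-Whitney comparison of two VAF samples."""
    a, b = np.asarray(vafs_a, float), np.asarray(vafs_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both VAF lists must be non-empty")
    if test == "ks":
        res = sps.ks_2samp(a, b, alternative="two-sided", method="auto")
    elif test == "mannwhitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def heteroplasmy_level_bins(
    catalog: MutationCatalog, bin_edges: Sequence[float] = DEFAULT_VAF_BINS
) -> pd.Series:
    """Proportion of mutations per heteroplasmy-level bin.

    ``bin_edges`` must be increasing and end at 1 (bins are
    left-open/right-closed and must partition (edge0, 1]).
    """
    edges = np.asarray(bin_edges, float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0) or edges[-1] != 1.0:
        raise ValueError("bin edges must be increasing and partition (low, 1]")
    vafs = catalog.vafs
    counts, _ = np.histogram(vafs, bins=edges)
    labels = [f"({edges[i]:g},{edges[i+1]:g}]" for i in range(len(edges) - 1)]
    total = counts.sum()
    return pd.Series(counts / total if total else np.nan, index=labels, name="proportion")


# ---------------------------------------------------------------------------
# HVS / non-HVS


def hvs_nonhvs_analysis(catalog: MutationCatalog, model: MitoGenomeModel) -> dict:
    """Observed vs length-expected non-HVS share of control-region
    mutations, with densities and a heteroplasmy comparison.

    Under relaxed selection the observed (non-HVS, HVS) counts follow
    the length split; the chi-square goodness-of-fit tests that
    expectation. Returns a flagged, test-free result when the catalog
    holds no control-region mutations.
    """
    df = catalog.mutations
    ctr = df.loc[df["in_ctr"].astype(bool)] if len(df) else df
    expected_pct = model.nonhvs_length_fraction()
    out: dict = {"expected_nonhvs_pct": expected_pct, "n_ctr_mutations": int(len(ctr))}
    if len(ctr) == 0:
        out["flag"] = "no control-region mutations; no test performed"
        return out
    is_nonhvs = (ctr["hvs"] == "non-HVS").to_numpy()
    n_non, n_hvs = int(is_nonhvs.sum()), int((~is_nonhvs).sum())
    n = n_non + n_hvs
    p_exp = expected_pct / 100.0
    chi2, p = sps.chisquare([n_non, n_hvs], f_exp=[n * p_exp, n * (1 - p_exp)])
    out.update(
        observed_nonhvs_pct=100.0 * n_non / n,
        counts={"non-HVS": n_non, "HVS": n_hvs},
        chi2=float(chi2),
        p=float(p),
        density_hvs=mutation_density(catalog, "HVS", model).density,
        density_nonhvs=mutation_density(catalog, "non-HVS", model).density,
    )
    hvs_vafs = ctr.loc[~is_nonhvs, "t_vaf"]
    non_vafs = ctr.loc[is_nonhvs, "t_vaf"]
    if len(hvs_vafs) and len(non_vafs):
        stat, pv = compare_heteroplasmy(hvs_vafs, non_vafs, test="mannwhitney")
        out["heteroplasmy_mw"] = {"statistic": stat, "p": pv}
    return out


# ---------------------------------------------------------------------------
# DssH regression and normalized complex densities


def dssh_density_regression(
    catalog: MutationCatalog,
    model: MitoGenomeModel,
    substitution_class: str = "C_H>T_H",
    correlation: str = "pearson",
) -> dict:
    """Gene-specific density of one substitution class against gene-mean
    DssH across the 13 protein genes, with correlation and OLS fit.

    A positive slope is the signature of replication-coupled
    mutagenesis: genes whose parental heavy strand stays single-stranded
    longer accumulate more C_H>T_H mutations per kb, absent selection.
    """
    df = catalog.mutations
    sub = df.loc[df["strand_class"] == substitution_class] if len(df) else df
    rows = []
    for gene in model.protein_genes():
        mask = model.mask(gene.name)
        n = int(mask[sub["position"].to_numpy()].sum()) if len(sub) else 0
        length = int(mask.sum())
        rows.append(
            {
                "gene": gene.name,
                "complex": gene.complex_membership,
                "mean_dss": model.gene_mean_dssh(gene.name),
                "n_mutations": n,
                "density": (n / catalog.n_samples) / (length / 1000.0),
            }
        )
    genes = pd.DataFrame(rows)
    if (genes["n_mutations"] > 0).sum() < 3:
        raise ValueError("need mutations in at least 3 protein genes for the regression")
    x, y = genes["mean_dss"].to_numpy(), genes["density"].to_numpy()
    if correlation == "pearson":
        r, p = sps.pearsonr(x, y)
    elif correlation == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation {correlation!r}")
    fit = sps.linregress(x, y)
    return {
        "per_gene": genes,
        "r": float(r),
        "p": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "substitution_class": substitution_class,
        "correlation": correlation,
    }


def complex_mean_dssh(model: MitoGenomeModel, complex_name: str) -> float:
    """Length-weighted mean DssH over a complex's member genes."""
    genes = [f for f in model.protein_genes() if f.complex_membership == complex_name]
    if not genes:
        raise KeyError(f"no genes in complex {complex_name!r}")
    lengths = np.array([g.length(model.genome_length) for g in genes], float)
    means = np.array([model.gene_mean_dssh(g.name) for g in genes])
    return float(np.average(means, weights=lengths))


def normalized_complex_density(
    catalog: MutationCatalog,
    model: MitoGenomeModel,
    substitution_class: str = "C_H>T_H",
    regression: dict | None = None,
) -> pd.DataFrame:
    """Per-complex observed and replication-normalized C_H>T_H densities.

    The standardization score of complex c is the regression-fitted
    density at c's length-weighted mean DssH divided by the fitted
    density at Complex IV's mean DssH (Complex IV, the least-exposed
    complex, scores 1 by construction, so its normalized density equals
    its observed density). A non-positive fitted density triggers a
    degeneracy warning and the raw density is reported unnormalized.
    """
    reg = regression or dssh_density_regression(catalog, model, substitution_class)
    slope, intercept = reg["slope"], reg["intercept"]
    df = catalog.mutations
    sub = df.loc[df["strand_class"] == substitution_class] if len(df) else df
    base = slope * complex_mean_dssh(model, "IV") + intercept
    rows = []
    for cx in ("I", "III", "IV", "V"):
        mask = model.mask(f"Com {cx}")
        length = int(mask.sum())
        n = int(mask[sub["position"].to_numpy()].sum()) if len(sub) else 0
        density = (n / catalog.n_samples) / (length / 1000.0)
        mean_dss = complex_mean_dssh(model, cx)
        fitted = slope * mean_dss + intercept
        if fitted <= 0 or base <= 0:
            import warnings

            warnings.warn(
                f"non-positive fitted density for complex {cx}; reporting raw density",
                stacklevel=2,
            )
            score, normalized = np.nan, density
        else:
            score = fitted / base
            normalized = density / score
        rows.append(
            {
                "complex": f"Com {cx}",
                "length_bp": length,
                "n_mutations": n,
                "mean_dss": mean_dss,
                "observed_density": density,
                "standardization_score": score,
                "normalized_density": normalized,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tRNA stem/loop


def trna_stem_loop_analysis(catalog: MutationCatalog, model: MitoGenomeModel) -> dict:
    """Stem vs non-stem (loop + variable) mutation density inside tRNAs.

    Tests the observed stem/non-stem counts against the length split
    (chi-square), breaks densities down per stem/loop arm pair, and
    reports deleterious (Watson-Crick-disrupting) proportions for stem
    vs non-stem mutations.
    """
    df = catalog.mutations
    trna = df.loc[df["trna_element"].notna() & (df["trna_element"] != "unclassified")] if len(df) else df
    out: dict = {"n_trna_mutations": int(len(trna))}
    if len(trna) == 0:
        out["flag"] = "no tRNA mutations; no test performed"
        return out

    stem_len = model.region_length("tRNA-stem")
    nonstem_len = model.region_length("tRNA-nonstem")
    from .genome import STEM_ELEMENTS

    is_stem = trna["trna_element"].isin(STEM_ELEMENTS).to_numpy()
    n_stem, n_nonstem = int(is_stem.sum()), int((~is_stem).sum())
    n = n_stem + n_nonstem
    p_stem = stem_len / (stem_len + nonstem_len)
    chi2, p = sps.chisquare([n_stem, n_nonstem], f_exp=[n * p_stem, n * (1 - p_stem)])
    out.update(
        stem_density=(n_stem / catalog.n_samples) / (stem_len / 1000.0),
        nonstem_density=(n_nonstem / catalog.n_samples) / (nonstem_len / 1000.0),
        counts={"stem": n_stem, "nonstem": n_nonstem},
        chi2=float(chi2),
        p=float(p),
        class_counts={
            part: trna.loc[mask_part, "strand_class"].value_counts().to_dict()
            for part, mask_part in (("stem", is_stem), ("nonstem", ~is_stem))
        },
    )

    pairs = []
    for arm in ("D", "anticodon", "T"):
        stem_label, loop_label = f"{arm}-stem", f"{arm}-loop"
        sl = sum(
            1
            for g in model.trna_structures.element.values()
            for e in g.values()
            if e == stem_label
        )
        ll = sum(
            1
            for g in model.trna_structures.element.values()
            for e in g.values()
            if e == loop_label
        )
        ns = int((trna["trna_element"] == stem_label).sum())
        nl = int((trna["trna_element"] == loop_label).sum())
        pairs.append(
            {
                "arm": arm,
                "stem_density": (ns / catalog.n_samples) / (sl / 1000.0),
                "loop_density": (nl / catalog.n_samples) / (ll / 1000.0),
                "n_stem": ns,
                "n_loop": nl,
            }
        )
    out["per_arm"] = pd.DataFrame(pairs)

    labeled = trna.loc[trna["deleteriousness"].notna()]
    if len(labeled):
        stem_lab = labeled.loc[labeled["trna_element"].isin(STEM_ELEMENTS)]
        loop_lab = labeled.loc[~labeled["trna_element"].isin(STEM_ELEMENTS)]
        out["deleterious_proportion"] = {
            "stem": float((stem_lab["deleteriousness"] == "deleterious").mean())
            if len(stem_lab)
            else np.nan,
            "nonstem": float((loop_lab["deleteriousness"] == "deleterious").mean())
            if len(loop_lab)
            else np.nan,
        }
    return out


def rrna_vs_ctr_heteroplasmy(catalog: MutationCatalog, model: MitoGenomeModel) -> dict:
    """Mann-Whitney comparison of rRNA vs control-region heteroplasmy."""
    df = catalog.mutations
    rmask = model.mask("rRNA")
    rrna = df.loc[rmask[df["position"].to_numpy()], "t_vaf"] if len(df) else pd.Series(dtype=float)
    ctr = df.loc[df["in_ctr"].astype(bool), "t_vaf"] if len(df) else pd.Series(dtype=float)
    if len(rrna) == 0 or len(ctr) == 0:
        return {"flag": "one group empty; no test performed", "n_rrna": len(rrna), "n_ctr": len(ctr)}
    stat, p = compare_heteroplasmy(rrna, ctr, test="mannwhitney")
    return {
        "statistic": stat,
        "p": p,
        "mean_vaf_rrna": float(rrna.mean()),
        "mean_vaf_ctr": float(ctr.mean()),
        "n_rrna": int(len(rrna)),
        "n_ctr": int(len(ctr)),
    }


def split_by_mutation_load(catalog: MutationCatalog, sample_ids: Sequence[str]) -> dict:
    """High/low mutation-load split of a cohort at the median per-sample
    mutation count (utility; downstream survival analysis is out of
    scope here)."""
    counts = catalog.mutations["sample_id"].value_counts()
    per_sample = pd.Series(0, index=list(sample_ids), dtype=int)
    per_sample.loc[counts.index] = counts
    median = float(per_sample.median())
    return {
        "median": median,
        "high": sorted(per_sample.index[per_sample > median]),
        "low": sorted(per_sample.index[per_sample <= median]),
    }


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are the default)."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# full report


@dataclass
class SelectionReport:
    """Every comparison of the analysis, in deterministic order."""

    sections: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, pd.DataFrame):
                return o.to_dict("records")
            if isinstance(o, pd.Series):
                return o.to_dict()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, RegionDensity):
                return {
                    "region": o.region,
                    "length_bp": o.length_bp,
                    "n_mutations": o.n_mutations,
                    "n_samples": o.n_samples,
                    "density": o.density,
                }
            raise TypeError(f"not serializable: {type(o)}")

        return json.dumps(self.sections, indent=2, sort_keys=True, default=default)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "selection_report.json").write_text(self.to_json() + "\n")
        for name, section in self.sections.items():
            if isinstance(section, pd.DataFrame):
                section.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)


def build_selection_report(
    catalog: MutationCatalog, model: MitoGenomeModel | None = None
) -> SelectionReport:
    """Run every analysis section on an annotated catalog.

    Sections mirror the study's comparisons: functional-region
    proportions, coding effects, strand spectra, heteroplasmy levels,
    mtCTR vs mtCDR, HVS vs non-HVS, DssH regression with normalized
    complex densities, tRNA stem/loop, and rRNA vs mtCTR heteroplasmy.
    Empty catalogs produce flagged empty sections rather than errors.
    """
    model = model or MitoGenomeModel.bundled()
    df = catalog.mutations
    report = SelectionReport()
    s = report.sections
    s["summary"] = {
        "n_mutations": int(len(df)),
        "n_samples": catalog.n_samples,
        "mean_mutations_per_sample": catalog.mean_mutations_per_sample(),
        "genome_density": mutation_density(catalog, "genome", model),
    }
    if len(df) == 0:
        s["flag"] = "empty catalog; all sections skipped"
        return report

    cats = df["region_category"].value_counts(normalize=True).sort_index()
    s["region_proportions"] = cats.rename_axis("region").reset_index(name="proportion")
    s["coding_effects"] = (
        df.loc[df["coding_effect"] != "noncoding", "coding_effect"]
        .value_counts(normalize=True)
        .rename_axis("effect")
        .reset_index(name="proportion")
    )
    s["spectrum_genome"] = spectrum_proportions(catalog, "genome", model).reset_index(
        names="class"
    )
    s["spectrum_mtCTR"] = spectrum_proportions(catalog, "mtCTR", model).reset_index(
        names="class"
    )
    s["spectrum_mtCDR"] = spectrum_proportions(catalog, "mtCDR", model).reset_index(
        names="class"
    )
    try:
        s["spectrum_ctr_vs_cdr_chi2"] = compare_spectra(catalog, "mtCTR", "mtCDR", model)
    except ValueError:
        s["spectrum_ctr_vs_cdr_chi2"] = {"flag": "insufficient counts"}
    s["heteroplasmy_bins"] = heteroplasmy_level_bins(catalog)
    s["density_mtCTR"] = mutation_density(catalog, "mtCTR", model)
    s["density_mtCDR"] = mutation_density(catalog, "mtCDR", model)
    ctr_vafs = df.loc[df["in_ctr"].astype(bool), "t_vaf"]
    cdr_vafs = df.loc[~df["in_ctr"].astype(bool), "t_vaf"]
    if len(ctr_vafs) and len(cdr_vafs):
        ks_stat, ks_p = compare_heteroplasmy(ctr_vafs, cdr_vafs, test="ks")
        s["heteroplasmy_ctr_vs_cdr_ks"] = {"statistic": ks_stat, "p": ks_p}
    s["hvs_nonhvs"] = hvs_nonhvs_analysis(catalog, model)
    try:
        reg = dssh_density_regression(catalog, model)
        s["dssh_regression"] = {k: v for k, v in reg.items() if k != "per_gene"}
        s["dssh_per_gene"] = reg["per_gene"]
        s["normalized_complex_density"] = normalized_complex_density(
            catalog, model, regression=reg
        )
    except ValueError as exc:
        s["dssh_regression"] = {"flag": str(exc)}
    s["trna_stem_loop"] = trna_stem_loop_analysis(catalog, model)
    s["rrna_vs_ctr_heteroplasmy"] = rrna_vs_ctr_heteroplasmy(catalog, model)
    return report
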