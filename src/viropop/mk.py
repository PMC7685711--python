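"""Polarized McDonald-Kreitman counts and the Direction of Selection.

Sites arrive pre-classified as synonymous or nonsynonymous; two outgroup
alleles polarize each variable site as either a substitution fixed on
the focal lineage or a derived polymorphism.  The Direction of
Selection, DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps), is positive when amino-acid
substitutions are in excess over amino-acid polymorphism, the signature
of adaptive fixation.  Per-gene contrasts subtract the median of a
background gene set, either genome-wide or restricted to neighbours.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "classify_site", "polarize_and_count", "dos", "dos_table",
    "background_contrast", "category_enrichment",
]

_FUNCTIONAL_CLASSES = ("synonymous", "nonsynonymous")


def classify_site(focal_alleles: Sequence[str], outgroup1: str, outgroup2: str,
                  drop_singletons: bool = True) -> str:
    """Status of one site: fixed_focal_branch, derived_polymorphic,
    singleton (excluded when drop_singletons) or uninformative.

    Polarization requires the two outgroups to agree on the ancestral
    allele; discordant outgroups are uninformative, as are sites whose
    focal alleles cannot be anchored to the ancestral state.
    """
    alleles = list(focal_alleles)
    if not alleles:
        return "uninformative"
    if outgroup1 != outgroup2:
        return "uninformative"
    anc = outgroup1
    distinct = sorted(set(alleles))
    if len(distinct) == 1:
        return "fixed_focal_branch" if distinct[0] != anc else "uninformative"
    if len(distinct) == 2 and anc in distinct:
        derived = distinct[0] if distinct[1] == anc else distinct[1]
        n_derived = sum(a == derived for a in alleles)
        if drop_singletons and n_derived == 1:
            return "singleton"
        return "derived_polymorphic"
    return "uninformative"


def polarize_and_count(sites: pd.DataFrame, drop_singletons: bool = True
                       ) -> pd.DataFrame:
    """Accumulate per-gene (Dn, Ds, Pn, Ps) from per-site calls.

    ``sites`` needs columns gene, functional_class, focal_alleles (a
    sequence or string of one character per focal sample), outgroup1,
    outgroup2.  Counting is invariant to sample order and site order.
    """
    required = {"gene", "functional_class", "focal_alleles", "outgroup1", "outgroup2"}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"sites table missing columns: {sorted(missing)}")
    counts: dict[str, dict[str, int]] = {}
    for row in sites.itertuples(index=False):
        fc = row.functional_class
        if fc not in _FUNCTIONAL_CLASSES:
            raise ValueError(f"site in gene {row.gene!r} has no valid functional "
                             f"class (got {fc!r})")
        gene_counts = counts.setdefault(
            row.gene, {"Dn": 0, "Ds": 0, "Pn": 0, "Ps": 0})
        status = classify_site(row.focal_alleles, row.outgroup1, row.outgroup2,
                               drop_singletons)
        if status == "fixed_focal_branch":
            gene_counts["Dn" if fc == "nonsynonymous" else "Ds"] += 1
        elif status == "derived_polymorphic":
            gene_counts["Pn" if fc == "nonsynonymous" else "Ps"] += 1
    out = pd.DataFrame.from_dict(counts, orient="index").rename_axis("gene")
    return out.reset_index()


def dos(dn: float, ds: float, pn: float, ps: float) -> float:
    """Direction of Selection; NaN when either ratio is undefined."""
    if dn + ds <= 0 or pn + ps <= 0:
        return float("nan")
    return dn / (dn + ds) - pn / (pn + ps)


def dos_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Add DoS and a reason column for undefined genes."""
    out = counts.copy()
    d_tot = out["Dn"] + out["Ds"]
    p_tot = out["Pn"] + out["Ps"]
    with np.errstate(divide="ignore", invalid="ignore"):
        val = out["Dn"] / d_tot - out["Pn"] / p_tot
    val = val.where((d_tot > 0) & (p_tot > 0))
    out["DoS"] = val
    reason = np.where(d_tot <= 0, "no substitutions",
                      np.where(p_tot <= 0, "no polymorphisms", ""))
    out["dos_reason"] = reason
    return out


def background_contrast(table: pd.DataFrame, value_col: str = "DoS",
                        scope: str = "genome_wide", local_window: int = 100_000,
                        min_background: int = 2) -> pd.DataFrame:
    """Per-gene delta of a statistic from the median of background genes.

    genome_wide: background is every other gene with a defined value.
    local: background restricted to genes on the same chromosome whose
    midpoints lie within ``local_window`` bp, excluding the gene itself.
    Genes whose background has fewer than ``min_background`` members get
    a missing delta.
    """
    if scope not in ("genome_wide", "local"):
        raise ValueError(f"unknown scope {scope!r}")
    out = table.copy()
    vals = out[value_col].to_numpy(dtype=float)
    deltas = np.full(len(out), np.nan)
    if scope == "local":
        chrom = out["chromosome"].to_numpy()
        mid = out["midpoint"].to_numpy(dtype=float)
    for i in range(len(out)):
        if not np.isfinite(vals[i]):
            continue
        mask = np.ones(len(out), dtype=bool)
        mask[i] = False
        if scope == "local":
            mask &= (chrom == chrom[i]) & (np.abs(mid - mid[i]) <= local_window)
        mask &= np.isfinite(vals)
        if mask.sum() < min_background:
            continue
        deltas[i] = vals[i] - np.median(vals[mask])
    out["delta"] = deltas
    return out


def category_enrichment(deltas: pd.DataFrame, n_boot: int = 10_000,
                        seed: int | None = None, ci: float = 0.95,
                        delta_col: str = "delta") -> pd.DataFrame:
    """Bootstrap mean delta per gene category with a percentile interval.

    Genes are resampled with replacement within category.  Categories
    with fewer than two genes with defined deltas are skipped with a
    warning.
    """
    rng = np.random.default_rng(seed)
    lo_q = (1 - ci) / 2
    rows = []
    for cat, grp in deltas.groupby("category", sort=True):
        vals = grp[delta_col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            logger.warning("category %r skipped: fewer than 2 genes with deltas", cat)
            continue
        boot = rng.choice(vals, size=(n_boot, len(vals)), replace=True).mean(axis=1)
        rows.append({
            "category": cat,
            "n_genes": len(vals),
            "mean_delta": float(vals.mean()),
            "ci_low": float(np.quantile(boot, lo_q)),
            "ci_high": float(np.quantile(boot, 1 - lo_q)),
        })
    return pd.DataFrame(rows)
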