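"""Per-SNP association of within-host allele frequency with log10 titer.

The model per locus is ordinary least squares,

    log10(titer) ~ SNP + sex + population + SNP:sex + PC1..PCm,

where the PCs are top eigenvectors of a centered genotype relationship
matrix, standing in for the kinship ("relationship[strain]") adjustment:
they capture sample relatedness driven by background variation.  To
avoid the relationship adjustment absorbing the very signal under test
(proximal contamination), the relationship matrix for each tested locus
excludes that locus and all loci in strong LD with it.

Genome-wide significance comes from a min-p permutation null (titer
labels permuted across infected samples), and the multilocus-haplotype
signal is tested by permuting titer within populations and comparing
the High-vs-Low titer gap against its permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GenotypeMatrix
from .linkage import pairwise_r2

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationNull", "filter_and_clump", "fit_titer_gwas", "bh_fdr",
    "minp_permutation_threshold", "haplotype_permutation_test",
]


@dataclass
class PermutationNull:
    """A permutation null distribution and its observed statistic."""

    n_permutations: int
    statistic: str                      # "min_p" or "high_low_difference"
    null: np.ndarray
    observed: float
    threshold: float | None = None      # only for min_p

    @property
    def empirical_p(self) -> float:
        null = np.asarray(self.null, dtype=float)
        if self.statistic == "min_p":
            extreme = np.sum(null <= self.observed)
        else:
            extreme = np.sum(null >= self.observed)
        return float((extreme + 1) / (len(null) + 1))


# ---------------------------------------------------------------------------
# filtering and clumping

def filter_and_clump(matrix: GenotypeMatrix, min_carriers: int = 5,
                     r2_threshold: float = 0.99, window: int = 10_000
                     ) -> GenotypeMatrix:
    """Drop rare loci, then merge near-duplicate loci within a window.

    A locus is kept when its consensus derived allele occurs in at least
    ``min_carriers`` infected samples.  Kept loci are then clumped
    greedily in position order: loci within ``window`` bp of a
    representative with pairwise r² >= ``r2_threshold`` are merged into
    it (the lowest position wins); merged member ids are recorded in a
    ``merged`` column of the locus table.
    """
    if matrix.n_loci == 0:
        raise ValueError("matrix has no loci")
    C = matrix.consensus()
    carriers = C.sum(axis=0)
    keep = carriers[carriers >= min_carriers].index
    sub = matrix.subset_loci(keep)
    if sub.n_loci == 0:
        loci = sub.loci.copy()
        loci["merged"] = pd.Series(dtype=str)
        return GenotypeMatrix(freq=sub.freq, loci=loci)

    ld = pairwise_r2(sub)
    r2 = ld.r2
    pos = sub.loci["position"].to_numpy()
    ids = list(sub.loci.index)
    L = len(ids)
    assigned = np.zeros(L, dtype=bool)
    reps: list[int] = []
    members: dict[int, list[int]] = {}
    for i in range(L):
        if assigned[i]:
            continue
        assigned[i] = True
        reps.append(i)
        members[i] = []
        for j in range(i + 1, L):
            if assigned[j] or pos[j] - pos[i] > window:
                continue
            if np.isfinite(r2[i, j]) and r2[i, j] >= r2_threshold:
                assigned[j] = True
                members[i].append(j)
    rep_ids = [ids[i] for i in reps]
    out = sub.subset_loci(rep_ids)
    out.loci = out.loci.copy()
    out.loci["merged"] = [",".join(ids[j] for j in members[i]) for i in reps]
    return out


# ---------------------------------------------------------------------------
# OLS machinery

def _encode_covariates(samples: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = {}
    for name in covariates:
        if name not in samples.columns:
            raise ValueError(f"covariate {name!r} not found in sample table")
        s = samples[name]
        if s.dtype == bool:
            cols[name] = s.astype(float)
        elif pd.api.types.is_numeric_dtype(s):
            cols[name] = s.astype(float)
        elif "date" in name:
            parsed = pd.to_datetime(s, errors="raise")
            cols[name] = (parsed - parsed.min()).dt.days.astype(float)
        else:
            dummies = pd.get_dummies(s, prefix=name, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float)
    return pd.DataFrame(cols, index=samples.index)


class _GwasEngine:
    """Shared state for the GWAS and its permutation procedures.

    Builds one fixed design matrix per locus (SNP column at index 1) so
    refits under permuted phenotypes reduce to matrix products.
    """

    def __init__(self, matrix: GenotypeMatrix, samples: pd.DataFrame,
                 covariates=("sex", "population"),
                 n_relationship_components: int = 5,
                 grm_exclude_r2: float = 0.5,
                 min_infected: int = 10):
        samples = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
        common = [s for s in matrix.freq.index if s in samples.index]
        sub = samples.loc[common]
        infected = sub[sub["infected"].astype(bool)] if "infected" in sub.columns else sub
        if infected["log10_titer"].isna().any():
            raise ValueError("log10_titer missing for some infected samples")
        if len(infected) < min_infected:
            raise ValueError(
                f"need >= {min_infected} infected samples with titer, got {len(infected)}")
        self.sample_ids = list(infected.index)
        self.matrix = matrix.subset_samples(self.sample_ids)
        self.y = infected["log10_titer"].to_numpy(dtype=float)
        self.n = len(self.y)

        cov_df = _encode_covariates(infected.reset_index(), list(covariates))
        self.cov = cov_df.to_numpy(dtype=float)
        self.cov_names = list(cov_df.columns)
        self.sex_col = None
        for i, c in enumerate(self.cov_names):
            if c == "sex" or c.startswith("sex_"):
                self.sex_col = i
                break

        self.F = self.matrix.freq.to_numpy(dtype=float)
        self.locus_ids = list(self.matrix.loci.index)
        self.r2 = pairwise_r2(self.matrix).r2
        self.n_pcs = int(n_relationship_components)
        self.grm_exclude_r2 = float(grm_exclude_r2)
        self._pc_cache: dict[bytes, np.ndarray] = {}
        self._designs: dict[int, tuple[np.ndarray, np.ndarray, float, int] | None] = {}

    # -- relationship eigenvectors --------------------------------------
    def _pcs_for(self, locus_index: int) -> np.ndarray:
        if self.n_pcs <= 0:
            return np.empty((self.n, 0))
        row = self.r2[locus_index]
        excl = np.zeros(len(self.locus_ids), dtype=bool)
        excl[locus_index] = True
        excl |= np.nan_to_num(row, nan=0.0) >= self.grm_exclude_r2
        if excl.sum() <= 1 and len(self.locus_ids) >= 20:
            # no LD partner and many loci: one global relationship matrix
            # serves all such loci (self-inclusion is a 1/L perturbation)
            excl = np.zeros_like(excl)
        key = excl.tobytes()
        if key not in self._pc_cache:
            Fi = self.F[:, ~excl]
            if Fi.shape[1] == 0:
                self._pc_cache[key] = np.empty((self.n, 0))
            else:
                Z = Fi - Fi.mean(axis=0)
                K = (Z @ Z.T) / Fi.shape[1]
                w, v = np.linalg.eigh(K)
                m = min(self.n_pcs, np.sum(w > 1e-10))
                self._pc_cache[key] = v[:, ::-1][:, :m] if m > 0 else np.empty((self.n, 0))
        return self._pc_cache[key]

    # -- per-locus design -----------------------------------------------
    def design(self, locus_index: int):
        """(X, pinv, cov11, dof) for one locus, or None if skipped."""
        if locus_index in self._designs:
            return self._designs[locus_index]
        f = self.F[:, locus_index]
        out = None
        if np.ptp(f) > 0:
            parts = [np.ones(self.n), f, *self.cov.T]
            if self.sex_col is not None:
                parts.append(f * self.cov[:, self.sex_col])
            X = np.column_stack(parts)
            pcs = self._pcs_for(locus_index)
            if pcs.size:
                X = np.column_stack([X, pcs])
            if np.linalg.matrix_rank(X) == X.shape[1] and self.n > X.shape[1]:
                pinv = np.linalg.pinv(X)
                cov11 = float((pinv @ pinv.T)[1, 1])
                out = (X, pinv, cov11, self.n - X.shape[1])
            else:
                logger.warning("locus %s skipped: singular design",
                               self.locus_ids[locus_index])
        else:
            logger.info("locus %s skipped: zero variance", self.locus_ids[locus_index])
        self._designs[locus_index] = out
        return out

    def testable(self) -> list[int]:
        return [i for i in range(len(self.locus_ids)) if self.design(i) is not None]

    # -- fitting ---------------------------------------------------------
    def fit_many(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """SNP-effect t statistics and p values for each locus x phenotype.

        Y is (n_samples, B); returns (L_testable, B) arrays aligned with
        ``testable()``.
        """
        idx = self.testable()
        B = Y.shape[1]
        T = np.full((len(idx), B), np.nan)
        P = np.full((len(idx), B), np.nan)
        for row, i in enumerate(idx):
            X, pinv, cov11, dof = self.design(i)
            beta = pinv @ Y
            resid = Y - X @ beta
            sigma2 = (resid**2).sum(axis=0) / dof
            se = np.sqrt(np.maximum(sigma2 * cov11, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = beta[1] / se
            T[row] = t
            P[row] = 2 * stats.t.sf(np.abs(t), dof)
        return T, P

    def fit_observed(self) -> pd.DataFrame:
        idx = self.testable()
        rows = []
        y = self.y[:, None]
        for i in idx:
            X, pinv, cov11, dof = self.design(i)
            beta = pinv @ self.y
            resid = self.y - X @ beta
            sigma2 = float(resid @ resid) / dof
            se = float(np.sqrt(max(sigma2 * cov11, 0.0)))
            t = beta[1] / se if se > 0 else np.nan
            p = 2 * stats.t.sf(abs(t), dof) if np.isfinite(t) else np.nan
            rows.append({
                "locus_id": self.locus_ids[i],
                "effect": float(beta[1]),
                "se": se,
                "t": float(t),
                "p": float(p),
            })
        return pd.DataFrame(
            rows, columns=["locus_id", "effect", "se", "t", "p"],
        ).set_index("locus_id")


def fit_titer_gwas(matrix: GenotypeMatrix, samples: pd.DataFrame,
                   covariates=("sex", "population"),
                   n_relationship_components: int = 5,
                   grm_exclude_r2: float = 0.5) -> pd.DataFrame:
    """Per-locus association between allele frequency and log10 titer.

    Returns one row per testable locus with the SNP main-effect estimate
    (change in log10 titer per unit allele frequency), its standard
    error, t and p, and the BH q value.  Monomorphic or collinear loci
    are skipped with a logged reason.
    """
    engine = _GwasEngine(matrix, samples, covariates,
                         n_relationship_components, grm_exclude_r2)
    res = engine.fit_observed()
    if len(res):
        res["q"] = bh_fdr(res["p"].to_numpy())
    else:
        res["q"] = pd.Series(dtype=float)
    return res


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q values, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# permutation procedures

def _permutation_matrix(y: np.ndarray, n_perm: int, rng: np.random.Generator,
                        groups: np.ndarray | None = None) -> np.ndarray:
    """(n, n_perm) matrix of permuted phenotypes (optionally within groups)."""
    n = len(y)
    Y = np.empty((n, n_perm))
    if groups is None:
        for b in range(n_perm):
            Y[:, b] = y[rng.permutation(n)]
    else:
        group_idx = [np.flatnonzero(groups == g) for g in np.unique(groups)]
        for b in range(n_perm):
            perm = np.arange(n)
            for gi in group_idx:
                perm[gi] = gi[rng.permutation(len(gi))]
            Y[:, b] = y[perm]
    return Y


def minp_permutation_threshold(matrix: GenotypeMatrix, samples: pd.DataFrame,
                               n_perm: int = 1000, alpha: float = 0.01,
                               seed: int | None = None,
                               covariates=("sex", "population"),
                               n_relationship_components: int = 5
                               ) -> tuple[float, PermutationNull]:
    """Genome-wide significance threshold from the min-p permutation null.

    Titer labels are permuted across infected samples; every locus is
    refit per permutation and the genome-wide minimum p recorded.  The
    threshold is the empirical alpha quantile of that null.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; the threshold will be noisy", n_perm)
    rng = np.random.default_rng(seed)
    engine = _GwasEngine(matrix, samples, covariates, n_relationship_components)
    Y = _permutation_matrix(engine.y, n_perm, rng)
    _, P = engine.fit_many(Y)
    null_minp = np.nanmin(P, axis=0)
    _, P_obs = engine.fit_many(engine.y[:, None])
    observed = float(np.nanmin(P_obs))
    k = max(1, int(np.floor(alpha * n_perm)))
    threshold = float(np.sort(null_minp)[k - 1])
    return threshold, PermutationNull(
        n_permutations=n_perm, statistic="min_p", null=null_minp,
        observed=observed, threshold=threshold)


def haplotype_permutation_test(matrix: GenotypeMatrix, samples: pd.DataFrame,
                               n_perm: int = 1000,
                               mode: str = "per_perm_top_snp",
                               focal_locus: str | None = None,
                               seed: int | None = None,
                               n_partners: int = 10,
                               stratify_by_population: bool = True,
                               covariates=("sex", "population"),
                               n_relationship_components: int = 5
                               ) -> PermutationNull:
    """Permutation test of the High-vs-Low multilocus titer difference.

    Per permutation (titer shuffled within populations), the top SNP by
    p value (or a supplied fixed locus) and its ``n_partners`` most
    strongly linked loci define a pseudo-haplotype; the statistic is the
    mean log10-titer difference between samples carrying all derived
    alleles and samples carrying none.  The empirical p compares the
    observed difference against this null.
    """
    if mode not in ("per_perm_top_snp", "fixed_focal"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "fixed_focal" and focal_locus is None:
        raise ValueError("fixed_focal mode requires focal_locus")
    rng = np.random.default_rng(seed)
    engine = _GwasEngine(matrix, samples, covariates, n_relationship_components)
    if len(engine.locus_ids) < n_partners + 1:
        raise ValueError(f"need >= {n_partners + 1} loci")
    groups = None
    if stratify_by_population:
        tab = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
        groups = tab.loc[engine.sample_ids, "population"].to_numpy()
    Y = _permutation_matrix(engine.y, n_perm, rng, groups)

    C = engine.matrix.consensus().to_numpy()
    r2 = engine.r2

    mask_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def masks_for(locus_index: int):
        if locus_index not in mask_cache:
            row = np.nan_to_num(r2[locus_index], nan=-1.0).copy()
            row[locus_index] = -np.inf
            partners = np.argsort(row, kind="stable")[::-1][:n_partners]
            group = np.concatenate([[locus_index], partners])
            sub = C[:, group]
            mask_cache[locus_index] = (sub.all(axis=1), (sub == 0).all(axis=1))
        return mask_cache[locus_index]

    def difference(yvec: np.ndarray, locus_index: int) -> float:
        m_all, m_none = masks_for(locus_index)
        if not m_all.any() or not m_none.any():
            return 0.0
        return float(yvec[m_all].mean() - yvec[m_none].mean())

    testable = engine.testable()
    if mode == "fixed_focal":
        if focal_locus not in engine.locus_ids:
            raise ValueError(f"focal locus {focal_locus!r} not in matrix")
        fixed_index = engine.locus_ids.index(focal_locus)
        top_per_perm = np.full(n_perm, fixed_index)
        obs_index = fixed_index
    else:
        _, P = engine.fit_many(Y)
        P = np.where(np.isfinite(P), P, 1.0)
        top_per_perm = np.asarray(testable)[np.argmin(P, axis=0)]
        _, P_obs = engine.fit_many(engine.y[:, None])
        P_obs = np.where(np.isfinite(P_obs), P_obs, 1.0)
        obs_index = testable[int(np.argmin(P_obs[:, 0]))]

    null = np.array([difference(Y[:, b], int(top_per_perm[b]))
                     for b in range(n_perm)])
    observed = difference(engine.y, obs_index)
    return PermutationNull(n_permutations=n_perm,
                           statistic="high_low_difference",
                           null=null, observed=observed)
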