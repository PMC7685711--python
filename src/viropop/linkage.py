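"""Linkage disequilibrium, four-gamete recombination screening and
multilocus haplotype typing.

All operations work on haploid consensus calls (derived allele iff the
within-host frequency is >= 0.5).  The four-gamete screen flags locus
pairs showing all four two-locus allele combinations, which under an
infinite-sites history implies recombination; flagged pairs are also
collapsed to a set of disjoint intervals so one genome-wide event count
can be reported without double-counting overlapping pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "LDMatrix", "FourGameteResult", "pairwise_r2", "four_gamete_scan",
    "classify_haplotype", "coinfection_screen", "merge_profiles",
    "partition_background_snps",
]


@dataclass
class LDMatrix:
    locus_ids: list[str]
    r2: np.ndarray  # symmetric, entries in [0, 1], NaN where undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.locus_ids, columns=self.locus_ids)


@dataclass
class FourGameteResult:
    pairs: pd.DataFrame       # locus_a, locus_b, n_distinct_gametes, recombination_signal
    n_flagged_pairs: int      # raw count of pairs showing all four gametes
    n_events: int             # flagged pairs collapsed to disjoint intervals


def pairwise_r2(matrix: GenotypeMatrix, loci=None) -> LDMatrix:
    """Pairwise r² between consensus genotypes.

    r² = (p_AB − p_A·p_B)² / (p_A(1−p_A)·p_B(1−p_B)), which for 0/1
    indicators is exactly the squared Pearson correlation.  Pairs
    involving a monomorphic locus are undefined and reported as NaN; the
    diagonal is 1 for polymorphic loci.
    """
    if loci is not None:
        matrix = matrix.subset_loci(loci)
    C = matrix.consensus().to_numpy(dtype=float)
    ids = list(matrix.loci.index)
    L = C.shape[1]
    out = np.full((L, L), np.nan)
    if C.shape[0] >= 2 and L >= 1:
        sd = C.std(axis=0)
        poly = sd > 0
        if poly.sum() >= 1:
            Z = (C[:, poly] - C[:, poly].mean(axis=0)) / sd[poly]
            corr = (Z.T @ Z) / C.shape[0]
            block = np.zeros((L, L))
            idx = np.flatnonzero(poly)
            out[np.ix_(idx, idx)] = corr**2
    return LDMatrix(locus_ids=ids, r2=out)


def four_gamete_scan(matrix: GenotypeMatrix, loci=None) -> FourGameteResult:
    """Screen all locus pairs for the presence of all four gametes.

    The recombination_signal flag is true iff the four two-locus
    combinations 00/01/10/11 all occur among samples.  ``n_events``
    collapses flagged pairs to a maximal set of disjoint genomic
    intervals (greedy by right endpoint; the Hudson–Kaplan lower bound),
    so overlapping pairs witnessing the same historical event are
    counted once.
    """
    if loci is not None:
        matrix = matrix.subset_loci(loci)
    C = matrix.consensus().to_numpy(dtype=np.int8)
    ids = list(matrix.loci.index)
    pos = matrix.loci["position"].to_numpy()
    L = C.shape[1]
    rows = []
    intervals = []
    for i in range(L):
        for j in range(i + 1, L):
            g = 2 * C[:, i] + C[:, j]
            n_distinct = len(np.unique(g))
            flag = n_distinct == 4
            rows.append((ids[i], ids[j], n_distinct, flag))
            if flag:
                intervals.append((pos[i], pos[j]))
    pairs = pd.DataFrame(
        rows, columns=["locus_a", "locus_b", "n_distinct_gametes", "recombination_signal"]
    )
    n_flagged = int(pairs["recombination_signal"].sum()) if len(pairs) else 0
    # greedy disjoint-interval count (open intervals: shared endpoint loci
    # can witness distinct events on either side)
    intervals.sort(key=lambda iv: iv[1])
    n_events = 0
    last_right = -np.inf
    for left, right in intervals:
        if left >= last_right:
            n_events += 1
            last_right = right
    return FourGameteResult(pairs=pairs, n_flagged_pairs=n_flagged, n_events=n_events)


def classify_haplotype(matrix: GenotypeMatrix, focal_loci=None,
                       segregation_band: tuple[float, float] = (0.05, 0.95)
                       ) -> pd.DataFrame:
    """Type each sample as High / Low / intermediate from its focal alleles.

    High carries the consensus derived allele at every focal locus, Low
    at none, anything else is intermediate.  Also counts focal loci
    segregating within the host (frequency strictly inside the band).
    """
    if focal_loci is None:
        focal_loci = matrix.focal_loci()
    focal_loci = list(focal_loci)
    missing = [l for l in focal_loci if l not in matrix.freq.columns]
    if missing:
        raise ValueError(f"focal loci missing from matrix: {missing}")
    if not focal_loci:
        raise ValueError("no focal loci supplied and none flagged in the matrix")
    F = matrix.freq.loc[:, focal_loci]
    C = (F >= 0.5).astype(int)
    n_high = C.sum(axis=1)
    lo, hi = segregation_band
    seg = ((F > lo) & (F < hi)).sum(axis=1)
    K = len(focal_loci)
    cls = np.where(n_high == K, "High", np.where(n_high == 0, "Low", "intermediate"))
    return pd.DataFrame({
        "sample_id": matrix.freq.index,
        "n_high_alleles": n_high.to_numpy(),
        "hap_class": cls,
        "segregating_focal_count": seg.to_numpy(),
    }).set_index("sample_id")


def coinfection_screen(matrix: GenotypeMatrix, focal_loci=None,
                       segregation_band: tuple[float, float] = (0.05, 0.95),
                       max_segregating: int = 2) -> pd.Series:
    """Flag samples as pure or mixed infections.

    A sample is called mixed iff more than ``max_segregating`` focal
    loci have within-host frequencies strictly inside the segregation
    band — the signature an artificial merge of a High and a Low sample
    produces at every focal locus.
    """
    calls = classify_haplotype(matrix, focal_loci, segregation_band)
    flags = np.where(calls["segregating_focal_count"] > max_segregating,
                     "mixed", "pure")
    return pd.Series(flags, index=calls.index, name="coinfection")


def merge_profiles(sample_a: pd.Series, sample_b: pd.Series, w: float) -> pd.Series:
    """Frequency profile of an artificial coinfection: w·a + (1−w)·b."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("weight w must be in [0, 1]")
    if set(sample_a.index) != set(sample_b.index):
        raise ValueError("samples must share an identical locus set")
    b = sample_b.reindex(sample_a.index)
    return w * sample_a + (1.0 - w) * b


def partition_background_snps(matrix: GenotypeMatrix,
                              populations: pd.Series,
                              calls: pd.DataFrame | None = None) -> dict:
    """Classify non-focal loci by their population/type sharing pattern.

    (a) ``population_private_shared_types``: derived allele present in a
    single population only, in at least one High and one Low sample
    there; (b) ``shared_across_pops_high_exclusive``: present in two or
    more populations and only ever in High samples; (c) ``other``.
    Returns per-class locus lists and counts.
    """
    pops = populations.reindex(matrix.freq.index)
    if pops.isna().any():
        raise ValueError("population label missing for some samples")
    if pops.nunique() < 2:
        raise ValueError("partition requires samples from >= 2 populations")
    if calls is None:
        calls = classify_haplotype(matrix)
    cls = calls["hap_class"].reindex(matrix.freq.index)
    C = matrix.consensus()
    focal = set(matrix.focal_loci())
    result: dict[str, list[str]] = {
        "population_private_shared_types": [],
        "shared_across_pops_high_exclusive": [],
        "other": [],
    }
    for locus in matrix.loci.index:
        if locus in focal:
            continue
        carriers = C[locus].to_numpy(dtype=bool)
        if not carriers.any():
            result["other"].append(locus)
            continue
        carrier_pops = set(pops[carriers])
        carrier_classes = set(cls[carriers])
        if len(carrier_pops) == 1 and {"High", "Low"} <= carrier_classes:
            result["population_private_shared_types"].append(locus)
        elif len(carrier_pops) >= 2 and carrier_classes <= {"High"}:
            result["shared_across_pops_high_exclusive"].append(locus)
        else:
            result["other"].append(locus)
    result["counts"] = {k: len(v) for k, v in result.items() if isinstance(v, list)}
    return result
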