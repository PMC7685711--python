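"""Synthetic cohorts of virus-infected flies with a planted two-type structure.

The generator emulates a field survey of four *Drosophila* populations whose
individuals are infected (at population-specific rates) with a large DNA
virus segregating for two multilocus genotypes: a "High" type carrying the
derived allele at all focal SNPs and a "Low" type carrying none.  Viral
titer (log10 genome copies per host genome) rises with the number of High
alleles with diminishing returns, reaching a configurable fold difference
(default 100x) for the full High type.  Background variation comprises
population-private SNPs shared between types, rarer shared SNPs exclusive
to High samples, unlinked noise SNPs, and an optional within-host
segregating locus modeled on the virus's Helicase-2 polymorphism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

GENOME_LENGTH = 155_000

#: positions of the 11 focal SNPs on the ~155 kb circular viral genome
FOCAL_POSITIONS = (
    14249, 41210, 42389, 59194, 59275, 59276, 66615, 78978, 78991, 126118, 140117
)
FOCAL_GENES = (
    "19K/PIF-4", "LEF-4", "gp83", "gp51", "PIF-6", "PIF-6",
    "gp19", "gp94", "gp94", "ODV-E56-2", "PIF-3",
)
FOCAL_ANNOTATIONS = (
    "nonsynonymous", "nonsynonymous", "upstream", "intergenic", "upstream",
    "upstream", "nonsynonymous", "intergenic", "intergenic", "upstream",
    "upstream",
)
SEGREGATING_POSITION = 132_593

_ANNOTATION_CLASSES = (
    "upstream", "downstream", "intergenic", "synonymous", "nonsynonymous", "nonsense"
)

_DEFAULT_POP_LABELS = ("HU", "SR", "CH", "PR")


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the cohort generator.

    Defaults reproduce the survey design: 57/92/92/92 flies in four
    populations with infection rates 26/44/71/79% and a 100-fold titer
    difference between the full High and Low viral types spread over 11
    linked focal SNPs with geometric-saturation diminishing returns.
    """

    n_populations: int = 4
    samples_per_population: tuple[int, ...] = (57, 92, 92, 92)
    infection_rate_per_population: tuple[float, ...] = (0.26, 0.44, 0.71, 0.79)
    high_type_freq_per_population: tuple[float, ...] = (0.30, 0.50, 0.71, 0.75)
    n_focal_loci: int = 11
    linkage_flip_rate: float = 0.01
    n_background_private: int = 15
    n_background_shared: int = 12
    n_noise_loci: int = 30
    mu_low_log10_titer: float = 3.0
    titer_sd_log10: float = 0.4
    full_fold_difference: float = 100.0
    diminishing_lambda: float = 0.7
    low_carrier_range: tuple[float, float] = (0.19, 0.94)
    shared_high_fraction_range: tuple[float, float] = (0.2, 0.6)
    include_segregating_locus: bool = True
    segregating_concentration: float = 8.0
    population_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        n = self.n_populations
        if n < 1:
            raise ValueError("n_populations must be >= 1")
        for name in ("samples_per_population", "infection_rate_per_population",
                     "high_type_freq_per_population"):
            vals = getattr(self, name)
            if len(vals) != n:
                raise ValueError(f"{name} must have length n_populations={n}")
        for name in ("infection_rate_per_population", "high_type_freq_per_population"):
            for v in getattr(self, name):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} entries must be probabilities in [0, 1]")
        if not 0.0 <= self.linkage_flip_rate <= 1.0:
            raise ValueError("linkage_flip_rate must be a probability in [0, 1]")
        if self.full_fold_difference <= 1.0:
            raise ValueError("full_fold_difference must be > 1")
        if not 0.0 < self.diminishing_lambda < 1.0:
            raise ValueError("diminishing_lambda must be in the open interval (0, 1)")
        if self.n_focal_loci < 1:
            raise ValueError("n_focal_loci must be >= 1")
        for name in ("n_background_private", "n_background_shared", "n_noise_loci"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.titer_sd_log10 < 0:
            raise ValueError("titer_sd_log10 must be >= 0")
        lo, hi = self.low_carrier_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("low_carrier_range must be an ordered pair in [0, 1]")
        lo, hi = self.shared_high_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("shared_high_fraction_range must be an ordered pair in (0, 1]")
        if self.population_labels is not None and len(self.population_labels) != n:
            raise ValueError("population_labels must have length n_populations")

    # -- convenience ----------------------------------------------------
    @property
    def pop_labels(self) -> tuple[str, ...]:
        if self.population_labels is not None:
            return tuple(self.population_labels)
        if self.n_populations == 4:
            return _DEFAULT_POP_LABELS
        return tuple(f"P{i + 1}" for i in range(self.n_populations))

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown CohortConfig keys: {sorted(unknown)}")
        d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
        return cls(**d)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in out.items()}


def mean_log10_titer(n_high_alleles: int, config: CohortConfig) -> float:
    """Expected log10 titer for a sample carrying ``k`` High alleles.

    mu(k) = mu_low + log10(F) * (1 - lam**k) / (1 - lam**K): monotone
    increasing with strictly decreasing increments, and mu(K) - mu(0) is
    exactly log10 of the configured fold difference.
    """
    k, K = n_high_alleles, config.n_focal_loci
    if not 0 <= k <= K:
        raise ValueError(f"n_high_alleles must be in [0, {K}], got {k}")
    lam = config.diminishing_lambda
    span = np.log10(config.full_fold_difference)
    return float(config.mu_low_log10_titer + span * (1 - lam**k) / (1 - lam**K))


def sample_titer(n_high_alleles: int, config: CohortConfig,
                 rng: np.random.Generator) -> float:
    """Draw a log10 titer: Normal(mu(k), titer_sd_log10)."""
    mu = mean_log10_titer(n_high_alleles, config)
    return float(rng.normal(mu, config.titer_sd_log10))


def _draw_positions(rng: np.random.Generator, n: int, taken: set[int]) -> list[int]:
    out: list[int] = []
    while len(out) < n:
        pos = int(rng.integers(1, GENOME_LENGTH + 1))
        if pos not in taken:
            taken.add(pos)
            out.append(pos)
    return out


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Generate a sample table and genotype matrix for one synthetic survey.

    Infected samples receive a latent viral type (High with the
    population's High frequency, else Low); each focal locus then flips
    independently with ``linkage_flip_rate``, producing occasional
    intermediate multilocus genotypes.  Titer is drawn from the
    diminishing-returns curve given the post-flip High-allele count.
    Background loci follow the planted partition: population-private loci
    are carried by every latent-High sample of their population and a
    uniform(0.19, 0.94) fraction of that population's Low samples;
    shared loci appear in a random subset of High samples spanning at
    least two populations and never in Low samples; noise loci are
    carried independently with a per-locus frequency ~ U(0.05, 0.5).

    Returns the full sample table (one row per fly, infected or not) and
    a genotype matrix restricted to infected samples.  Deterministic for
    a given config (the seed lives in the config).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pops = config.pop_labels
    K = config.n_focal_loci

    rows = []
    for p_idx, pop in enumerate(pops):
        n = config.samples_per_population[p_idx]
        rate = config.infection_rate_per_population[p_idx]
        for i in range(n):
            sex = "M" if rng.random() < 0.5 else "F"
            wolbachia = bool(rng.random() < 0.4)
            day = int(rng.integers(0, 21))  # survey window, late Aug-early Sep
            date = pd.Timestamp("2017-08-22") + pd.Timedelta(days=day)
            infected = bool(rng.random() < rate)
            rows.append({
                "sample_id": f"{pop}_{i + 1:03d}",
                "species": "D. innubila",
                "population": pop,
                "sex": sex,
                "wolbachia": wolbachia,
                "collection_date": date.date().isoformat(),
                "infected": infected,
                "log10_titer": np.nan,
            })
    samples = pd.DataFrame(rows)

    infected_mask = samples["infected"].to_numpy()
    inf_idx = np.flatnonzero(infected_mask)
    n_inf = len(inf_idx)
    inf_pop = samples["population"].to_numpy()[inf_idx]

    # latent type and focal genotypes
    high_freq = {pop: config.high_type_freq_per_population[i]
                 for i, pop in enumerate(pops)}
    latent_high = np.array([rng.random() < high_freq[p] for p in inf_pop])
    focal = np.tile(latent_high[:, None], (1, K)).astype(int)
    flips = rng.random((n_inf, K)) < config.linkage_flip_rate
    focal = np.where(flips, 1 - focal, focal)

    n_high = focal.sum(axis=1)
    titers = np.array([sample_titer(int(k), config, rng) for k in n_high])
    samples.loc[samples.index[inf_idx], "log10_titer"] = titers

    if n_inf == 0:
        loci = pd.DataFrame(
            columns=["position", "annotation", "gene", "focal", "focal_order"]
        ).rename_axis("locus_id")
        loci["position"] = loci["position"].astype(int)
        loci["focal"] = loci["focal"].astype(bool)
        freq = pd.DataFrame(index=pd.Index([], name="sample_id"))
        return samples, GenotypeMatrix(freq=freq, loci=loci)

    # ---- locus layout --------------------------------------------------
    taken: set[int] = set()
    if K == len(FOCAL_POSITIONS):
        focal_pos = list(FOCAL_POSITIONS)
        focal_gene = list(FOCAL_GENES)
        focal_ann = list(FOCAL_ANNOTATIONS)
    else:
        focal_pos = sorted(_draw_positions(rng, K, taken))
        focal_gene = [f"gene{j + 1}" for j in range(K)]
        focal_ann = [str(rng.choice(_ANNOTATION_CLASSES)) for _ in range(K)]
    taken.update(focal_pos)

    loci_rows = []
    columns: list[np.ndarray] = []

    for j in range(K):
        loci_rows.append({
            "locus_id": f"focal_{j + 1:02d}",
            "position": focal_pos[j],
            "annotation": focal_ann[j],
            "gene": focal_gene[j],
            "focal": True,
            "focal_order": j + 1,
        })
        columns.append(focal[:, j].astype(float))

    if config.include_segregating_locus:
        taken.add(SEGREGATING_POSITION)
        # within-host frequency bell-shaped against titer rank: Beta draws
        # whose mode tracks 4 r (1 - r), mirroring the non-monotone rank
        # relationship seen for the Helicase-2 polymorphism
        ranks = pd.Series(titers).rank(method="average").to_numpy()
        r = (ranks - 0.5) / n_inf
        mode = 0.05 + 0.9 * 4.0 * r * (1.0 - r)
        c = config.segregating_concentration
        a = 1.0 + mode * (c - 2.0)
        b = 1.0 + (1.0 - mode) * (c - 2.0)
        seg_freq = rng.beta(a, b)
        loci_rows.append({
            "locus_id": "seg_helicase",
            "position": SEGREGATING_POSITION,
            "annotation": "nonsynonymous",
            "gene": "Helicase-2-like",
            "focal": False,
            "focal_order": np.nan,
        })
        columns.append(seg_freq)

    # population-private background, shared between types within their pop
    pop_of_sample = inf_pop
    for p_idx, pop in enumerate(pops):
        in_pop = pop_of_sample == pop
        positions = _draw_positions(rng, config.n_background_private, taken)
        for jj, pos in enumerate(positions):
            lo, hi = config.low_carrier_range
            carrier_frac = rng.uniform(lo, hi)
            col = np.zeros(n_inf)
            col[in_pop & latent_high] = 1.0
            low_here = in_pop & ~latent_high
            col[low_here] = (rng.random(low_here.sum()) < carrier_frac).astype(float)
            loci_rows.append({
                "locus_id": f"priv_{pop}_{jj + 1:02d}",
                "position": pos,
                "annotation": str(rng.choice(_ANNOTATION_CLASSES)),
                "gene": f"bg_{pop}_{jj + 1}",
                "focal": False,
                "focal_order": np.nan,
            })
            columns.append(col)

    # shared across populations, exclusive to (a subset of) High samples
    positions = _draw_positions(rng, config.n_background_shared, taken)
    high_idx = np.flatnonzero(latent_high)
    for jj, pos in enumerate(positions):
        lo, hi = config.shared_high_fraction_range
        frac = rng.uniform(lo, hi)
        col = np.zeros(n_inf)
        if len(high_idx) > 0:
            for _ in range(100):
                carriers = high_idx[rng.random(len(high_idx)) < frac]
                if len(set(pop_of_sample[carriers])) >= 2 or len(set(pop_of_sample[high_idx])) < 2:
                    break
            col[carriers] = 1.0
        loci_rows.append({
            "locus_id": f"shared_{jj + 1:02d}",
            "position": pos,
            "annotation": str(rng.choice(_ANNOTATION_CLASSES)),
            "gene": f"sh_{jj + 1}",
            "focal": False,
            "focal_order": np.nan,
        })
        columns.append(col)

    # unlinked noise loci
    positions = _draw_positions(rng, config.n_noise_loci, taken)
    for jj, pos in enumerate(positions):
        q = rng.uniform(0.05, 0.5)
        col = (rng.random(n_inf) < q).astype(float)
        loci_rows.append({
            "locus_id": f"noise_{jj + 1:02d}",
            "position": pos,
            "annotation": str(rng.choice(_ANNOTATION_CLASSES)),
            "gene": f"ns_{jj + 1}",
            "focal": False,
            "focal_order": np.nan,
        })
        columns.append(col)

    loci = pd.DataFrame(loci_rows).set_index("locus_id")
    order = np.argsort(loci["position"].to_numpy(), kind="stable")
    loci = loci.iloc[order]
    freq = pd.DataFrame(
        np.column_stack(columns)[:, order],
        index=pd.Index(samples["sample_id"].to_numpy()[inf_idx], name="sample_id"),
        columns=loci.index,
    )
    matrix = GenotypeMatrix(freq=freq, loci=loci)
    matrix.validate()
    return samples, matrix


def generate_mk_counts(
    n_genes_per_category: Mapping[str, int],
    category_dn_inflation: Mapping[str, float],
    base_rates: Sequence[float],
    seed: int | None = None,
) -> pd.DataFrame:
    """Poisson-distributed per-gene McDonald-Kreitman count tables.

    ``base_rates`` gives the expected (Dn, Ds, Pn, Ps) per gene; each
    category's Dn expectation is multiplied by its inflation, mimicking
    gene classes (e.g. envelope) with an excess of fixed amino-acid
    substitutions.  Genes get a chromosome label and increasing midpoints
    so local background contrasts are exercised.
    """
    dn, ds, pn, ps = (float(x) for x in base_rates)
    for name, v in zip(("Dn", "Ds", "Pn", "Ps"), (dn, ds, pn, ps)):
        if v < 0:
            raise ValueError(f"base rate {name} must be >= 0")
    for cat, infl in category_dn_inflation.items():
        if infl <= 0:
            raise ValueError(f"inflation for category {cat!r} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    mid = 0
    for cat, n_genes in n_genes_per_category.items():
        infl = float(category_dn_inflation.get(cat, 1.0))
        for i in range(n_genes):
            mid += int(rng.integers(2_000, 20_000))
            rows.append({
                "gene": f"{cat}_{i + 1}",
                "category": cat,
                "Dn": int(rng.poisson(dn * infl)),
                "Ds": int(rng.poisson(ds)),
                "Pn": int(rng.poisson(pn)),
                "Ps": int(rng.poisson(ps)),
                "chromosome": "viral",
                "midpoint": mid,
            })
    return pd.DataFrame(rows)
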