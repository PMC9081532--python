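"""Synthetic cohorts with known ground truth.

The generative model mirrors the linear-mixture assumption the refitting
step makes: each sample of a cancer type draws signature exposures from a
Dirichlet centered on the type's mean exposure profile, a mutation burden
from a log-normal (exome scale, default median 200 SNVs, floor 10), and its
96-channel counts from a multinomial over catalog^T . exposures.  Driver
gene mutations are Bernoulli at type-specific frequencies over a sparse
background.  Metastases re-draw their primary's exposures at high Dirichlet
concentration (low "drift") and resample counts; cfDNA samples are binomial
thinnings of their tissue sample with per-gene mutation dropout.

What this emulates: type-specific exposure structure, count noise at
realistic burdens, enriched drivers, clustered-vs-random PPI neighborhoods,
primary/metastasis sharing, and cfDNA dilution.  What it does not: genomic
positions, clonal structure, sequencing artifacts, indel/CNV signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import SignatureCatalog
from .network import PPINetwork
from .spectrum import Spectrum96

DEFAULT_BURDEN = (math.log(200.0), 0.8)  # log-normal (mu, sigma) of SNV burden
BURDEN_FLOOR = 10
BACKGROUND_MUTATION_RATE = 0.01
GENE_POOL_SIZE = 500


class ConfigurationError(ValueError):
    pass


def gene_pool(size: int = GENE_POOL_SIZE) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, size + 1)]


@dataclass
class CancerTypeProfile:
    """Ground-truth description of one synthetic cancer type."""

    type_name: str
    exposure_mean: np.ndarray  # over catalog signatures, sums to 1
    specific_signatures: list[str]
    driver_gene_freqs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exposure_mean = np.asarray(self.exposure_mean, dtype=float)
        if abs(self.exposure_mean.sum() - 1) > 1e-9:
            raise ConfigurationError(
                f"{self.type_name}: exposure_mean sums to {self.exposure_mean.sum()}"
            )
        if (self.exposure_mean < 0).any():
            raise ConfigurationError(f"{self.type_name}: negative exposure mean")

    def validate_against(self, catalog: SignatureCatalog) -> None:
        if len(self.exposure_mean) != len(catalog):
            raise ConfigurationError(
                f"{self.type_name}: exposure_mean length {len(self.exposure_mean)} "
                f"!= catalog size {len(catalog)}"
            )
        for sig in self.specific_signatures:
            if sig not in catalog.names:
                raise ConfigurationError(
                    f"{self.type_name}: specific signature {sig!r} not in catalog"
                )
            if self.exposure_mean[catalog.names.index(sig)] < 0.15:
                raise ConfigurationError(
                    f"{self.type_name}: planted signature {sig!r} mean below 0.15"
                )


@dataclass
class SampleTruth:
    type_name: str
    exposures: np.ndarray  # non-negative, sums to 1
    mutation_count: int
    compartment: str = "tissue"  # tissue | metastasis | cfdna
    paired_primary_id: str | None = None


@dataclass
class SyntheticTruth:
    seed: int
    samples: dict[str, SampleTruth] = field(default_factory=dict)

    def add(self, sample_id: str, truth: SampleTruth) -> None:
        if truth.compartment != "tissue" and truth.paired_primary_id not in self.samples:
            raise ConfigurationError(
                f"{sample_id}: paired primary {truth.paired_primary_id!r} unknown"
            )
        self.samples[sample_id] = truth

    def types(self) -> pd.Series:
        return pd.Series({sid: t.type_name for sid, t in self.samples.items()})

    def exposures_df(self, signature_names: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            [t.exposures for t in self.samples.values()],
            index=pd.Index(list(self.samples), name="sample_id"),
            columns=signature_names,
        )

    def ids_in(self, compartment: str) -> list[str]:
        return [s for s, t in self.samples.items() if t.compartment == compartment]


def _dirichlet_on_support(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw allowing zero concentrations (zero mass stays zero)."""
    out = np.zeros_like(alpha, dtype=float)
    mask = alpha > 0
    if mask.sum() == 1:
        out[mask] = 1.0
    else:
        out[mask] = rng.dirichlet(alpha[mask])
    return out


def _draw_burden(rng: np.random.Generator, burden_dist: tuple[float, float]) -> int:
    mu, sigma = burden_dist
    return max(BURDEN_FLOOR, int(round(rng.lognormal(mu, sigma))))


def simulate_cohort(
    profiles: list[CancerTypeProfile],
    n_per_type: int,
    catalog: SignatureCatalog,
    seed: int,
    burden_dist: tuple[float, float] = DEFAULT_BURDEN,
    concentration: float = 50.0,
    genes: list[str] | None = None,
    background_rate: float = BACKGROUND_MUTATION_RATE,
    id_prefix: str = "S",
) -> tuple[list[Spectrum96], pd.DataFrame, SyntheticTruth]:
    """Draw a labeled multi-type cohort.

    Per sample: exposures ~ Dirichlet(concentration * type mean) — or the
    mean itself when concentration is infinite —, burden ~ log-normal with
    floor 10, channel counts ~ Multinomial(burden, catalog^T exposures),
    and gene mutations ~ Bernoulli(driver frequency, background elsewhere).
    """
    if n_per_type < 1:
        raise ConfigurationError("n_per_type must be >= 1")
    if concentration <= 0:
        raise ConfigurationError("concentration must be > 0")
    for pr in profiles:
        pr.validate_against(catalog)
    genes = list(genes) if genes is not None else gene_pool()
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    spectra: list[Spectrum96] = []
    gene_rows: list[np.ndarray] = []
    ids: list[str] = []
    driver_prob = {
        pr.type_name: np.array(
            [pr.driver_gene_freqs.get(g, background_rate) for g in genes]
        )
        for pr in profiles
    }
    for pr in profiles:
        for i in range(n_per_type):
            sid = f"{id_prefix}_{pr.type_name}_{i:04d}"
            if np.isinf(concentration):
                expo = pr.exposure_mean.copy()
            else:
                expo = _dirichlet_on_support(rng, concentration * pr.exposure_mean)
            n_mut = _draw_burden(rng, burden_dist)
            channel_p = catalog.matrix.T @ expo
            counts = rng.multinomial(n_mut, channel_p / channel_p.sum())
            spectra.append(Spectrum96(sid, counts))
            gene_rows.append((rng.random(len(genes)) < driver_prob[pr.type_name]).astype(np.int64))
            ids.append(sid)
            truth.add(sid, SampleTruth(pr.type_name, expo, n_mut))
    gene_matrix = pd.DataFrame(
        gene_rows, index=pd.Index(ids, name="sample_id"), columns=genes
    )
    return spectra, gene_matrix, truth


def simulate_metastases(
    truth: SyntheticTruth,
    catalog: SignatureCatalog,
    n_pairs: int,
    drift: float,
    seed: int,
    source_ids: list[str] | None = None,
    burden_dist: tuple[float, float] = DEFAULT_BURDEN,
) -> tuple[list[Spectrum96], SyntheticTruth]:
    """Add metastases copying primaries' exposures up to Dirichlet drift.

    Each metastasis re-draws its primary's exposure vector from a Dirichlet
    with concentration 1/drift (small drift = faithful copy), then
    resamples counts at a fresh burden.  Pairing is recorded in the truth.
    """
    if drift <= 0:
        raise ConfigurationError("drift must be > 0")
    pool = source_ids if source_ids is not None else truth.ids_in("tissue")
    if n_pairs > len(pool):
        raise ConfigurationError(f"n_pairs={n_pairs} exceeds {len(pool)} tissue samples")
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(pool, size=n_pairs, replace=False)) if n_pairs else []
    spectra: list[Spectrum96] = []
    for primary_id in chosen:
        prim = truth.samples[primary_id]
        expo = _dirichlet_on_support(rng, prim.exposures / drift)
        n_mut = _draw_burden(rng, burden_dist)
        channel_p = catalog.matrix.T @ expo
        counts = rng.multinomial(n_mut, channel_p / channel_p.sum())
        sid = f"MET_{primary_id}"
        spectra.append(Spectrum96(sid, counts))
        truth.add(
            sid,
            SampleTruth(
                prim.type_name, expo, n_mut,
                compartment="metastasis", paired_primary_id=primary_id,
            ),
        )
    return spectra, truth


def simulate_cfdna(
    truth: SyntheticTruth,
    tissue_spectra: list[Spectrum96],
    gene_matrix: pd.DataFrame,
    dilution: float,
    dropout: float,
    seed: int,
    source_ids: list[str] | None = None,
) -> tuple[list[Spectrum96], pd.DataFrame, SyntheticTruth]:
    """Derive cfDNA samples by thinning paired tissue samples.

    Channel counts are Binomial(count, dilution) per channel; each planted
    gene mutation is independently dropped with probability ``dropout``.
    """
    if not (0 < dilution <= 1):
        raise ConfigurationError("dilution must be in (0, 1]")
    if not (0 <= dropout < 1):
        raise ConfigurationError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    by_id = {s.sample_id: s for s in tissue_spectra}
    pool = source_ids if source_ids is not None else [s.sample_id for s in tissue_spectra]
    spectra: list[Spectrum96] = []
    gene_rows: list[np.ndarray] = []
    ids: list[str] = []
    for tid in pool:
        tissue = by_id[tid]
        counts = rng.binomial(tissue.counts, dilution)
        sid = f"CF_{tid}"
        spectra.append(Spectrum96(sid, counts))
        row = gene_matrix.loc[tid].to_numpy()
        kept = row * (rng.random(len(row)) >= dropout)
        gene_rows.append(kept.astype(np.int64))
        ids.append(sid)
        src = truth.samples[tid]
        truth.add(
            sid,
            SampleTruth(
                src.type_name, src.exposures.copy(), int(counts.sum()),
                compartment="cfdna", paired_primary_id=tid,
            ),
        )
    cf_genes = pd.DataFrame(
        gene_rows, index=pd.Index(ids, name="sample_id"), columns=gene_matrix.columns
    )
    return spectra, cf_genes, truth


def simulate_ppi(
    cancer_gene_module: list[str],
    background_genes: int,
    p_in: float,
    p_out: float,
    seed: int,
) -> PPINetwork:
    """A planted-module random graph: dense inside the module, sparse outside."""
    if p_in <= p_out:
        raise ConfigurationError("p_in must exceed p_out")
    module = [g.strip().upper() for g in cancer_gene_module]
    background = [f"BG{i:04d}" for i in range(1, background_genes + 1)]
    nodes = module + background
    in_module = set(module)
    rng = np.random.default_rng(seed)
    edges = []
    n = len(nodes)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    draws = rng.random(len(pairs))
    for (i, j), u in zip(pairs, draws):
        p = p_in if (nodes[i] in in_module and nodes[j] in in_module) else p_out
        if u < p:
            edges.append((nodes[i], nodes[j]))
    net = PPINetwork.from_edges(edges)
    net.graph.add_nodes_from(nodes)
    return net


def simulate_mutation_sets(
    module: list[str],
    all_genes: list[str],
    n_samples: int,
    n_mutations: int,
    mode: str,
    seed: int,
) -> list[set[str]]:
    """Per-sample mutated gene sets, functionally clustered or random.

    ``mode="module"`` draws half of each sample's mutations from the planted
    module (clustered mutagenesis); ``mode="random"`` draws uniformly from
    the full gene pool.
    """
    rng = np.random.default_rng(seed)
    module = [g.strip().upper() for g in module]
    all_genes = [g.strip().upper() for g in all_genes]
    out: list[set[str]] = []
    for _ in range(n_samples):
        if mode == "module":
            k_mod = min(len(module), max(1, n_mutations // 2))
            picked = set(rng.choice(module, size=k_mod, replace=False))
            rest = [g for g in all_genes if g not in picked]
            extra = n_mutations - len(picked)
            if extra > 0:
                picked |= set(rng.choice(rest, size=min(extra, len(rest)), replace=False))
        elif mode == "random":
            picked = set(rng.choice(all_genes, size=min(n_mutations, len(all_genes)), replace=False))
        else:
            raise ConfigurationError(f"unknown mode {mode!r}")
        out.append(picked)
    return out


# ---------------------------------------------------------------------------
# Default catalogs and profiles


def block_catalog(n_signatures: int, name_prefix: str = "S") -> SignatureCatalog:
    """Disjoint-support toy catalog: signature i uniform over its channel block."""
    if not (1 <= n_signatures <= 96):
        raise ConfigurationError("n_signatures must be in 1..96")
    mat = np.zeros((n_signatures, 96))
    bounds = np.linspace(0, 96, n_signatures + 1).astype(int)
    for i in range(n_signatures):
        lo, hi = bounds[i], bounds[i + 1]
        mat[i, lo:hi] = 1.0 / (hi - lo)
    return SignatureCatalog([f"{name_prefix}{i + 1}" for i in range(n_signatures)], mat)


def random_catalog(n_signatures: int, seed: int, alpha: float = 0.3) -> SignatureCatalog:
    """Sparse random catalog: rows are Dirichlet(alpha) over the 96 channels."""
    rng = np.random.default_rng(seed)
    mat = rng.dirichlet(np.full(96, alpha), size=n_signatures)
    return SignatureCatalog([f"S{i + 1}" for i in range(n_signatures)], mat)


DEFAULT_TYPE_NAMES = [
    "NSCLC", "OV", "BLCA", "BRCA", "LIHC", "STAD", "ESCA", "COAD", "PAAD", "PRAD",
]


def default_profiles(
    catalog: SignatureCatalog,
    type_names: list[str] | None = None,
    specific_weight: float = 0.4,
    n_drivers: int = 3,
    driver_freq: float = 0.4,
    genes: list[str] | None = None,
) -> list[CancerTypeProfile]:
    """One profile per type: signature i planted as type i's specific
    signature at mean ``specific_weight``, the remainder spread over shared
    background signatures (the last two catalog entries), plus
    ``n_drivers`` enriched driver genes per type.
    """
    type_names = type_names or DEFAULT_TYPE_NAMES
    if len(catalog) < len(type_names) + 2:
        raise ConfigurationError(
            f"catalog needs >= {len(type_names) + 2} signatures for "
            f"{len(type_names)} types plus 2 shared backgrounds"
        )
    genes = list(genes) if genes is not None else gene_pool()
    profiles = []
    for i, name in enumerate(type_names):
        mean = np.zeros(len(catalog))
        mean[i] = specific_weight
        mean[-2] = (1 - specific_weight) / 2
        mean[-1] = (1 - specific_weight) / 2
        drivers = {
            genes[i * n_drivers + j]: driver_freq for j in range(n_drivers)
        }
        profiles.append(
            CancerTypeProfile(
                type_name=name,
                exposure_mean=mean,
                specific_signatures=[catalog.names[i]],
                driver_gene_freqs=drivers,
            )
        )
    return profiles
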