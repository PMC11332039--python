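"""Forward simulator for hierarchically structured coral genotype surveys.

The generator is the F-model run forwards.  Each locus has an ancestral
allele frequency drawn from Uniform(0.05, 0.95).  Species-level
frequencies are Balding-Nichols draws around the ancestral frequency
with drift parameter ``f_species``; island-within-species frequencies
are Balding-Nichols draws around the species frequency with
``f_island``.  Diploid genotypes are Binomial(2, p) samples from the
island frequency.  For environment-associated ("selected") loci the
island frequency is shifted on the logit scale by
``cline_slope * z_island`` where ``z_island`` is the standardized island
environment score, mimicking a temperature cline.

The sampling design emulates a basin-scale multi-island survey:
11 islands x ~3 sites x ~3 colonies, with a handful of latent species
in sympatry, strongly inter-correlated per-site temperature descriptors
driven by a single latent gradient tied to island longitude, and exact
clonal replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import MISSING, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_dataset",
    "inject_missingness",
    "plant_clone_groups",
    "simulate_allele_counts",
    "write_metadata_tsv",
    "write_environment_tsv",
    "write_truth_tsv",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model.

    Drift parameters are on the FST scale: ``f_species`` is the expected
    differentiation among species around the ancestral frequency and
    ``f_island`` the differentiation among islands within a species.
    ``cline_slope`` is the logit-scale allele-frequency displacement per
    unit of standardized island environment score at selected loci.
    """

    n_species: int = 3
    n_islands: int = 11
    sites_per_island: int = 3
    samples_per_site: int = 3
    n_sites_genomic: int = 5000
    contig_length_bp: int = 100_000
    f_species: float = 0.15
    f_island: float = 0.02
    n_selected: int = 0
    cline_slope: float = 2.0
    n_env_descriptors: int = 63
    env_island_sd: float = 1.0
    env_site_sd: float = 0.25
    n_clone_pairs: int = 0
    missing_rate: float = 0.0
    seed: int = 0
    sites_per_contig: int = 1000

    def __post_init__(self) -> None:
        for name in (
            "n_species", "n_islands", "sites_per_island", "samples_per_site",
            "n_sites_genomic", "contig_length_bp", "n_env_descriptors",
            "sites_per_contig",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_selected < 0 or self.n_clone_pairs < 0:
            raise ValueError("n_selected and n_clone_pairs must be >= 0")
        if not (0.0 < self.f_species < 1.0 and 0.0 < self.f_island < 1.0):
            raise ValueError("f_species and f_island must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_selected > self.n_sites_genomic:
            raise ValueError("n_selected cannot exceed n_sites_genomic")

    @property
    def n_samples(self) -> int:
        return self.n_islands * self.sites_per_island * self.samples_per_site


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset for parameter-recovery tests."""

    selected_site_ids: np.ndarray  # indices into the site axis
    island_freqs: np.ndarray  # (n_species, n_islands, n_sites) true frequencies
    clone_pairs: list[tuple[str, str]]  # (source, clone) sample-id pairs
    species_assignment: dict[str, str]
    island_gradient: np.ndarray  # standardized latent environment score per island
    island_labels: list[str] = field(default_factory=list)
    species_labels: list[str] = field(default_factory=list)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float, size) -> np.ndarray:
    """Beta(p(1-f)/f, (1-p)(1-f)/f) draws, the Balding-Nichols model."""
    scale = (1.0 - f) / f
    draws = rng.beta(np.broadcast_to(p * scale, size), np.broadcast_to((1.0 - p) * scale, size))
    return np.clip(draws, 1e-9, 1.0 - 1e-9)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate genotypes, sample metadata, a per-site environment table
    and the ground truth.

    Returns
    -------
    (GenotypeMatrix, metadata, environment, TruthTable)
        ``metadata`` has one row per sample with columns
        ``sample_id, island, site, lineage, lat, lon, depth_m``;
        ``environment`` is indexed by site id with
        ``n_env_descriptors`` mutually correlated temperature
        descriptor columns.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_sites_genomic
    S, I, K = config.n_species, config.n_islands, config.samples_per_site

    # --- site coordinates -------------------------------------------------
    n_contigs = int(np.ceil(L / config.sites_per_contig))
    contigs, positions = [], []
    left = L
    for c in range(n_contigs):
        take = min(config.sites_per_contig, left)
        left -= take
        pos = np.sort(rng.choice(config.contig_length_bp, size=take, replace=False)) + 1
        contigs.extend([f"ctg{c + 1:04d}"] * take)
        positions.extend(pos.tolist())
    contigs = np.array(contigs, dtype=object)
    positions = np.array(positions, dtype=np.int64)

    # --- geography and environment ---------------------------------------
    island_lon = np.linspace(-160.0, -80.0, I) + rng.normal(0.0, 1.0, I)
    island_lat = rng.uniform(-25.0, 15.0, I)
    if I > 1:
        grad = (island_lon - island_lon.mean()) / island_lon.std()
        grad = grad + rng.normal(0.0, 0.3, I)
        grad = (grad - grad.mean()) / grad.std()
    else:
        grad = np.zeros(I)

    island_names = [f"I{i + 1:02d}" for i in range(I)]
    site_rows = []
    for i in range(I):
        for s in range(config.sites_per_island):
            site_rows.append(
                {
                    "site": f"{island_names[i]}S{s + 1:02d}",
                    "island": island_names[i],
                    "island_idx": i,
                    "lat": island_lat[i] + rng.normal(0.0, 0.1),
                    "lon": island_lon[i] + rng.normal(0.0, 0.1),
                }
            )
    sites = pd.DataFrame(site_rows)

    D = config.n_env_descriptors
    slopes = rng.normal(1.0, 0.3, D) * rng.choice([-1.0, 1.0], D)
    intercepts = rng.normal(25.0, 3.0, D)
    env_vals = (
        intercepts[None, :]
        + config.env_island_sd * np.outer(grad[sites["island_idx"]], slopes)
        + rng.normal(0.0, config.env_site_sd, (len(sites), D))
    )
    environment = pd.DataFrame(
        env_vals,
        index=pd.Index(sites["site"], name="site_id"),
        columns=[f"sst_descriptor_{d + 1:02d}" for d in range(D)],
    )

    # --- allele frequencies (two-level Balding-Nichols) -------------------
    p_anc = rng.uniform(0.05, 0.95, L)
    p_species = _balding_nichols(rng, p_anc[None, :], config.f_species, (S, L))
    p_island = _balding_nichols(
        rng, p_species[:, None, :], config.f_island, (S, I, L)
    )
    selected = rng.choice(L, size=config.n_selected, replace=False)
    selected.sort()
    if config.n_selected:
        # species-specific cline strengths (mean multiplier 1): adaptation
        # to the same gradient differs among species, so selected loci
        # carry both an environment association and excess among-species
        # differentiation where the gradient is steep
        alt = np.array([(0, 1, -1)[k % 3] for k in range(S)], dtype=float)
        slope = config.cline_slope * (1.0 + 0.5 * alt)
        shift = slope[:, None, None] * grad[None, :, None]
        p_island[:, :, selected] = _expit(
            _logit(p_island[:, :, selected]) + shift
        )
        p_island = np.clip(p_island, 1e-9, 1.0 - 1e-9)

    # --- samples ----------------------------------------------------------
    species_names = [f"SP{s + 1}" for s in range(S)]
    sample_ids: list[str] = []
    meta_rows = []
    dosages = np.empty((config.n_samples, L), dtype=np.int8)
    species_of: dict[str, str] = {}
    counter = 0
    for si, site in sites.iterrows():
        i = int(site["island_idx"])
        for k in range(K):
            sp = (si * K + k) % S
            sid = f"{site['site']}C{counter + 1:03d}"
            dosages[counter] = rng.binomial(2, p_island[sp, i]).astype(np.int8)
            sample_ids.append(sid)
            species_of[sid] = species_names[sp]
            meta_rows.append(
                {
                    "sample_id": sid,
                    "island": site["island"],
                    "site": site["site"],
                    "lineage": species_names[sp],
                    "lat": site["lat"],
                    "lon": site["lon"],
                    "depth_m": float(np.clip(rng.normal(9.3, 3.9), 1.0, 30.0)),
                }
            )
            counter += 1
    metadata = pd.DataFrame(meta_rows)

    # --- clones: exact genotype copies within a site ----------------------
    clone_pairs: list[tuple[str, str]] = []
    if config.n_clone_pairs:
        eligible = metadata.groupby("site").filter(lambda g: len(g) >= 2)
        sites_with_pairs = list(eligible["site"].unique())
        rng.shuffle(sites_with_pairs)
        used: set[str] = set()
        for site_id in sites_with_pairs:
            if len(clone_pairs) >= config.n_clone_pairs:
                break
            members = metadata.loc[metadata["site"] == site_id, "sample_id"].tolist()
            members = [m for m in members if m not in used]
            if len(members) < 2:
                continue
            src, dst = members[0], members[1]
            i_src = sample_ids.index(src)
            i_dst = sample_ids.index(dst)
            dosages[i_dst] = dosages[i_src]
            species_of[dst] = species_of[src]
            metadata.loc[metadata["sample_id"] == dst, "lineage"] = species_of[src]
            clone_pairs.append((src, dst))
            used.update((src, dst))
        if len(clone_pairs) < config.n_clone_pairs:
            raise ValueError("not enough sites with >=2 samples to place clone pairs")

    qual = rng.uniform(30.0, 60.0, L)
    gm = GenotypeMatrix(dosages, sample_ids, contigs, positions, qual)
    if config.missing_rate > 0:
        gm = inject_missingness(gm, config.missing_rate, int(rng.integers(2**31)))

    truth = TruthTable(
        selected_site_ids=selected,
        island_freqs=p_island,
        clone_pairs=clone_pairs,
        species_assignment=species_of,
        island_gradient=grad,
        island_labels=island_names,
        species_labels=species_names,
    )
    return gm, metadata, environment, truth


def inject_missingness(gm: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set each genotype call to missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return gm
    rng = np.random.default_rng(seed)
    out = gm.copy()
    mask = rng.random(out.dosages.shape) < rate
    out.dosages[mask] = MISSING
    return out


def plant_clone_groups(
    gm: GenotypeMatrix, group_sizes: list[int], seed: int
) -> tuple[GenotypeMatrix, list[list[str]]]:
    """Overwrite genotypes so that disjoint sample groups become exact clones.

    Useful for recreating known clonal structures (e.g. six multilocus
    lineages shared among 14 specimens).  Returns the modified matrix and
    the list of clone groups (lists of sample ids; first member is the
    source genotype).
    """
    if sum(group_sizes) > gm.n_samples:
        raise ValueError("clone groups need more samples than available")
    rng = np.random.default_rng(seed)
    order = rng.permutation(gm.n_samples)
    out = gm.copy()
    groups: list[list[str]] = []
    cursor = 0
    for size in group_sizes:
        members = order[cursor : cursor + size]
        cursor += size
        src = members[0]
        for m in members[1:]:
            out.dosages[m] = out.dosages[src]
        groups.append([gm.sample_ids[m] for m in members])
    return out, groups


def simulate_allele_counts(
    n_loci: int,
    n_pops: int,
    samples_per_pop: int,
    beta: float | np.ndarray = -2.0,
    alpha: np.ndarray | None = None,
    seed: int = 0,
    p_anc: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate per-population allele counts directly under the logistic F-model.

    ``FST`` of locus l in population p is ``sigmoid(alpha_l + beta_p)``;
    population frequencies are Balding-Nichols draws at that FST around a
    Uniform(0.05, 0.95) ancestral frequency, and ALT counts are binomial
    out of ``2 * samples_per_pop`` alleles.

    ``p_anc`` entries that are not NaN override the drawn ancestral
    frequencies (useful to plant effects at informative mid-range loci:
    a locus whose ancestral frequency sits near a boundary drifts to
    fixation everywhere and carries no divergence signal).

    Returns ``(alt_counts, total_counts, p_anc)`` with shape (n_loci, n_pops).
    """
    rng = np.random.default_rng(seed)
    alpha = np.zeros(n_loci) if alpha is None else np.asarray(alpha, dtype=float)
    beta = np.broadcast_to(np.asarray(beta, dtype=float), (n_pops,))
    drawn = rng.uniform(0.05, 0.95, n_loci)
    if p_anc is not None:
        override = np.asarray(p_anc, dtype=float)
        drawn = np.where(np.isnan(override), drawn, override)
    p_anc = drawn
    fst = _expit(alpha[:, None] + beta[None, :])
    theta = (1.0 - fst) / fst
    p = rng.beta(theta * p_anc[:, None], theta * (1.0 - p_anc[:, None]))
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    total = np.full((n_loci, n_pops), 2 * samples_per_pop, dtype=np.int64)
    alt = rng.binomial(total, p)
    return alt, total, p_anc


# ---------------------------------------------------------------------------
# Plain-text writers
# ---------------------------------------------------------------------------

def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def write_environment_tsv(environment: pd.DataFrame, path) -> None:
    environment.to_csv(path, sep="\t")


def write_truth_tsv(truth: TruthTable, path) -> None:
    """Flat per-fact truth table (one row per fact, tagged by kind)."""
    with open(path, "w") as fh:
        fh.write("kind\tkey\tvalue\n")
        for sid in truth.selected_site_ids:
            fh.write(f"selected_site\t{sid}\t1\n")
        for src, dst in truth.clone_pairs:
            fh.write(f"clone_pair\t{src}\t{dst}\n")
        for sample, sp in truth.species_assignment.items():
            fh.write(f"species\t{sample}\t{sp}\n")
        for name, g in zip(truth.island_labels, truth.island_gradient):
            fh.write(f"island_gradient\t{name}\t{g:.6f}\n")
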