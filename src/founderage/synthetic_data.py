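"""Forward-in-time generator of founder-mutation case data with known truth.

A single founder chromosome is drawn from a control-like background pool; its
marker alleles define the ancestral haplotype. Descendant carrier chromosomes
accumulate, over ``g`` generations, recombination against the background pool
(per-interval, at most one switch per interval per meiosis) and per-marker
mutation (SNP flip; STR one-step with reflection at the allele-range bounds).
Controls are drawn i.i.d. from the pool.

Two genealogy modes are supported:

* ``star`` -- every sampled carrier is an independent lineage of depth exactly
  ``g`` (the estimators' null model);
* ``branching`` -- a Poisson(``r``) Galton-Watson process run for ``g``
  generations conditioned on survival (full resampling on extinction), the
  realistic genealogy used to calibrate the growth correction.

Recombination switches the remainder of the chromosome to a fresh pool draw
rather than tracking an explicit diploid pedigree, matching the
background-linkage-equilibrium assumption of the estimators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .genmap import Marker, MarkerMap, build_marker_map, read_marker_map_tsv, write_marker_map_tsv
from .haplotypes import HaplotypeDistribution

MAX_RESAMPLE_ATTEMPTS = 10_000
POPULATION_CAP = 2_000_000


class SimulationError(RuntimeError):
    """Simulation could not satisfy its conditioning."""


# ---------------------------------------------------------------------------
# Background pool

@dataclass
class BackgroundPool:
    """Control-chromosome pool: explicit haplotypes or independent sites.

    ``site_frequencies`` mode draws each marker independently from its allele
    frequencies (linkage equilibrium); ``haplotypes`` mode draws whole
    chromosomes from a weighted list (background LD).
    """

    mode: str
    site_freqs: list[np.ndarray] | None = None
    haplotypes: np.ndarray | None = None
    frequencies: np.ndarray | None = None

    @classmethod
    def from_site_frequencies(cls, freqs) -> "BackgroundPool":
        site = []
        for f in freqs:
            f = np.asarray(f, dtype=float)
            if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
                raise SimulationError("site frequencies must be >= 0 and sum to 1")
            site.append(f)
        return cls(mode="site_frequencies", site_freqs=site)

    @classmethod
    def from_haplotypes(cls, haplotypes, frequencies) -> "BackgroundPool":
        haps = np.asarray(haplotypes, dtype=np.int64)
        f = np.asarray(frequencies, dtype=float)
        if haps.ndim != 2 or haps.shape[0] != f.shape[0]:
            raise SimulationError("haplotype/frequency shape mismatch")
        if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
            raise SimulationError("pool frequencies must be >= 0 and sum to 1")
        return cls(mode="haplotypes", haplotypes=haps, frequencies=f)

    @property
    def n_markers(self) -> int:
        if self.mode == "site_frequencies":
            return len(self.site_freqs)
        return self.haplotypes.shape[1]

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n chromosomes as an (n, m) array of allele indices."""
        if self.mode == "haplotypes":
            idx = rng.choice(len(self.frequencies), size=n, p=self.frequencies)
            return self.haplotypes[idx].copy()
        out = np.empty((n, self.n_markers), dtype=np.int64)
        for j, f in enumerate(self.site_freqs):
            out[:, j] = rng.choice(len(f), size=n, p=f)
        return out

    def allele_frequencies(self) -> list[np.ndarray]:
        """Marginal allele-index frequencies per marker."""
        if self.mode == "site_frequencies":
            return [f.copy() for f in self.site_freqs]
        out = []
        for j in range(self.n_markers):
            k = self.haplotypes[:, j].max() + 1
            f = np.zeros(k)
            for h, w in zip(self.haplotypes[:, j], self.frequencies):
                f[h] += w
            out.append(f)
        return out


# ---------------------------------------------------------------------------
# Configuration and truth records

@dataclass
class SimConfig:
    g_true: int
    r: float
    n_cases: int
    n_controls: int
    marker_map: MarkerMap
    background_pool: BackgroundPool
    seed: int = 0
    genealogy: str = "star"
    emit_genotypes: bool = False
    max_attempts: int = MAX_RESAMPLE_ATTEMPTS

    def __post_init__(self):
        if self.g_true < 0:
            raise SimulationError("g_true must be >= 0")
        if self.r <= 0:
            raise SimulationError("growth rate r must be > 0")
        if self.n_cases < 1:
            raise SimulationError("n_cases must be >= 1")
        if self.genealogy not in ("star", "branching"):
            raise SimulationError(f"unknown genealogy mode {self.genealogy!r}")
        if self.background_pool.n_markers != len(self.marker_map):
            raise SimulationError("pool/map marker-count mismatch")


@dataclass
class SimTruth:
    """Generator ground truth for one simulated dataset."""

    g_true: int
    r: float
    genealogy: str
    ancestral_alleles: tuple[str, ...]
    lineage_count_trajectory: list[int]
    #: per sampled carrier chromosome: number of inside-out markers on each
    #: flank still descended from the founder segment
    intact_proximal: np.ndarray | None = None
    intact_distal: np.ndarray | None = None
    mutation_counts: np.ndarray | None = None

    def ancestral_core_bounds(self, mmap: MarkerMap) -> list[tuple[int, int]]:
        """Per carrier, (lowest, highest) marker index of the intact core.

        Returns marker-index bounds of the contiguous founder-descended
        segment around the locus; (-1, -1) marks an empty core side pair.
        """
        out = []
        prox, dist = mmap.side_orders()
        for kp, kd in zip(self.intact_proximal, self.intact_distal):
            idxs = [prox[j] for j in range(kp)] + [dist[j] for j in range(kd)]
            if idxs:
                out.append((min(idxs), max(idxs)))
            else:
                out.append((-1, -1))
        return out


@dataclass
class CaseControlDataset:
    """Estimator input: carrier haplotype distributions + control pool."""

    marker_map: MarkerMap
    carriers: list[HaplotypeDistribution]
    control_haplotypes: list[tuple[str, ...]]
    control_ids: list[str] = field(default_factory=list)
    genotypes: dict | None = None  # sample_id -> list of unordered allele pairs
    genotype_carrier_flags: dict | None = None  # sample_id -> 0/1


# ---------------------------------------------------------------------------
# Galton-Watson growth

def simulate_growth_lineages(
    g: int,
    r: float,
    rng: np.random.Generator,
    conditioned: bool = True,
    counts_only: bool = False,
    max_attempts: int = MAX_RESAMPLE_ATTEMPTS,
):
    """Poisson(``r``) Galton-Watson process for ``g`` generations.

    Returns ``(trajectory, parents)``: per-generation copy counts starting at
    1, and (unless ``counts_only``) per-generation arrays mapping each copy to
    its parent's index in the previous generation. When ``conditioned`` the
    process is resampled until >= 1 copy survives at generation ``g`` (cap
    ``max_attempts``); unconditioned runs may return a trajectory ending in 0.
    """
    if g < 0:
        raise SimulationError("g must be >= 0")
    if r <= 0:
        raise SimulationError("r must be > 0")
    attempts = max_attempts if conditioned else 1
    for _ in range(attempts):
        traj = [1]
        parents: list[np.ndarray] | None = None if counts_only else []
        n = 1
        for _t in range(g):
            if n == 0:
                traj.append(0)
                if not counts_only:
                    parents.append(np.empty(0, dtype=np.int64))
                continue
            if counts_only:
                n_next = int(rng.poisson(r * n))
            else:
                offspring = rng.poisson(r, size=n)
                n_next = int(offspring.sum())
                parents.append(np.repeat(np.arange(n), offspring))
                # memory guard: only parent tracking materializes the tree
                if n_next > POPULATION_CAP:
                    raise SimulationError(
                        f"population exceeded cap {POPULATION_CAP}; lower r or g"
                    )
            traj.append(n_next)
            n = n_next
        if not conditioned or n > 0:
            return traj, parents
    raise SimulationError(
        f"extinction in all {max_attempts} resampling attempts (r={r}, g={g})"
    )


def extinction_probability(r: float) -> float:
    """Ultimate extinction probability of the Poisson(r) Galton-Watson process.

    Smallest fixed point of s = exp(r (s - 1)); 1 when r <= 1.
    """
    from scipy.optimize import brentq

    if r <= 1:
        return 1.0
    return brentq(lambda s: np.exp(r * (s - 1.0)) - s, 0.0, 1.0 - 1e-12)


# ---------------------------------------------------------------------------
# Meiosis on blocks of chromosomes

def _apply_meiosis(
    alleles: np.ndarray,
    intact_prox: np.ndarray,
    intact_dist: np.ndarray,
    mut_counts: np.ndarray,
    mmap: MarkerMap,
    pool: BackgroundPool,
    rng: np.random.Generator,
) -> None:
    """Apply one meiosis in place to a block of chromosomes.

    Per flank, each inter-marker (and locus-flank) interval recombines with
    probability ``theta_interval``; each switch replaces the chromosome from
    that interval outward with a fresh pool draw. Then each marker mutates
    with its per-generation rate.
    """
    n = alleles.shape[0]
    for order, intact in (
        (mmap.proximal_order, intact_prox),
        (mmap.distal_order, intact_dist),
    ):
        k = len(order)
        if k == 0:
            continue
        theta = mmap.theta_interval[list(order)]
        rec = rng.random((n, k)) < theta
        for j in range(k):
            rows = np.flatnonzero(rec[:, j])
            if rows.size:
                fresh = pool.draw(rows.size, rng)
                cols = list(order[j:])
                alleles[np.ix_(rows, cols)] = fresh[:, cols]
                mut_counts[np.ix_(rows, cols)] = 0
        any_rec = rec.any(axis=1)
        first = np.where(any_rec, rec.argmax(axis=1), k)
        np.minimum(intact, first, out=intact)

    for j, marker in enumerate(mmap.markers):
        mu = marker.mutation_rate
        if mu <= 0.0:
            continue
        hit = np.flatnonzero(rng.random(n) < mu)
        if hit.size == 0:
            continue
        k_alleles = len(marker.alleles)
        cur = alleles[hit, j]
        if marker.marker_type.endswith("_str"):
            step = rng.choice((-1, 1), size=hit.size)
            new = cur + step
            new[new < 0] = 1 if k_alleles > 1 else 0
            new[new >= k_alleles] = k_alleles - 2
        elif k_alleles == 2:
            new = 1 - cur
        else:
            new = (cur + rng.integers(1, k_alleles, size=hit.size)) % k_alleles
        alleles[hit, j] = new
        mut_counts[hit, j] += 1


def _labels(mmap: MarkerMap, row: np.ndarray) -> tuple[str, ...]:
    return tuple(mmap.markers[j].alleles[int(a)] for j, a in enumerate(row))


def simulate_dataset(config: SimConfig):
    """Simulate a case-control dataset and its ground truth.

    Returns ``(CaseControlDataset, SimTruth)``. Raises
    :class:`SimulationError` when the conditioned branching population holds
    fewer surviving copies than ``n_cases``.
    """
    rng = np.random.default_rng(config.seed)
    mmap = config.marker_map
    pool = config.background_pool
    m = len(mmap)
    founder = pool.draw(1, rng)[0]
    kp, kd = len(mmap.proximal_order), len(mmap.distal_order)

    if config.genealogy == "star":
        n = config.n_cases
        alleles = np.tile(founder, (n, 1))
        intact_prox = np.full(n, kp, dtype=np.int64)
        intact_dist = np.full(n, kd, dtype=np.int64)
        mut_counts = np.zeros((n, m), dtype=np.int64)
        for _t in range(config.g_true):
            _apply_meiosis(alleles, intact_prox, intact_dist, mut_counts, mmap, pool, rng)
        trajectory = [1] + [n] * config.g_true if config.g_true else [1]
        sample_idx = np.arange(n)
    else:
        traj, parents = simulate_growth_lineages(
            config.g_true, config.r, rng, conditioned=True,
            max_attempts=config.max_attempts,
        )
        alleles = founder[None, :].copy()
        intact_prox = np.array([kp], dtype=np.int64)
        intact_dist = np.array([kd], dtype=np.int64)
        mut_counts = np.zeros((1, m), dtype=np.int64)
        for par in parents:
            alleles = alleles[par].copy()
            intact_prox = intact_prox[par].copy()
            intact_dist = intact_dist[par].copy()
            mut_counts = mut_counts[par].copy()
            _apply_meiosis(alleles, intact_prox, intact_dist, mut_counts, mmap, pool, rng)
        trajectory = traj
        n_final = alleles.shape[0]
        if n_final < config.n_cases:
            raise SimulationError(
                f"only {n_final} surviving copies for {config.n_cases} cases"
            )
        sample_idx = rng.choice(n_final, size=config.n_cases, replace=False)
        sample_idx.sort()

    case_alleles = alleles[sample_idx]
    carriers = [
        HaplotypeDistribution.certain(f"case{i + 1:04d}", _labels(mmap, row))
        for i, row in enumerate(case_alleles)
    ]
    control_rows = pool.draw(2 * config.n_controls, rng)
    control_haps = [_labels(mmap, row) for row in control_rows]
    control_ids = [
        f"ctrl{i // 2 + 1:04d}/{i % 2 + 1}" for i in range(len(control_haps))
    ]

    genotypes = None
    flags = None
    if config.emit_genotypes:
        genotypes = {}
        flags = {}
        mates = pool.draw(config.n_cases, rng)
        for i in range(config.n_cases):
            a = _labels(mmap, case_alleles[i])
            b = _labels(mmap, mates[i])
            genotypes[f"case{i + 1:04d}"] = [
                tuple(sorted(p)) for p in zip(a, b)
            ]
            flags[f"case{i + 1:04d}"] = 1
        for i in range(config.n_controls):
            a = control_haps[2 * i]
            b = control_haps[2 * i + 1]
            genotypes[f"ctrl{i + 1:04d}"] = [tuple(sorted(p)) for p in zip(a, b)]
            flags[f"ctrl{i + 1:04d}"] = 0

    dataset = CaseControlDataset(
        marker_map=mmap,
        carriers=carriers,
        control_haplotypes=control_haps,
        control_ids=control_ids,
        genotypes=genotypes,
        genotype_carrier_flags=flags,
    )
    truth = SimTruth(
        g_true=config.g_true,
        r=config.r,
        genealogy=config.genealogy,
        ancestral_alleles=_labels(mmap, founder),
        lineage_count_trajectory=[int(x) for x in trajectory],
        intact_proximal=intact_prox[sample_idx].copy(),
        intact_distal=intact_dist[sample_idx].copy(),
        mutation_counts=mut_counts[sample_idx].copy(),
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Fast single-marker decay (sufficient statistics of the same process)

def simulate_single_marker_pD(
    g: int,
    r: float,
    theta: float,
    p_anc: float,
    n_sample: int,
    n_reps: int,
    rng: np.random.Generator,
    genealogy: str = "branching",
    max_rounds: int = 200,
) -> np.ndarray:
    """Sampled carrier-allele frequencies p_D at one marker, vectorized.

    For the branching mode this marginalizes the Poisson Galton-Watson
    chromosome process to the pair (intact copies, total copies): offspring of
    intact parents are Poisson(r * I) of which Binomial(., 1 - theta) stay
    intact; the marginal law is identical to the full per-chromosome
    simulation. Replicates are conditioned on >= ``n_sample`` survivors. A
    non-intact sampled chromosome carries the ancestral allele with the pool
    frequency ``p_anc``. Replicates whose surviving population is smaller
    than ``n_sample`` sample every surviving chromosome instead (a young
    mutation cannot have more sampled carriers than copies).
    """
    if genealogy == "star":
        surv = (1.0 - theta) ** g
        intact = rng.binomial(n_sample, surv, size=n_reps)
        match = rng.binomial(n_sample - intact, p_anc)
        return (intact + match) / n_sample

    if genealogy != "branching":
        raise SimulationError(f"unknown genealogy mode {genealogy!r}")

    # beyond this size demographic fluctuations are negligible relative to the
    # sampled fraction, so growth and decay proceed at their expectations
    DETERMINISTIC_ABOVE = 1e9

    def run_block(k: int) -> tuple[np.ndarray, np.ndarray]:
        intact = np.ones(k)
        total = np.ones(k)
        for _t in range(g):
            small = total < DETERMINISTIC_ABOVE
            if np.any(small):
                ii = intact[small].astype(np.int64)
                tt = total[small].astype(np.int64)
                off_intact = rng.poisson(r * ii)
                off_other = rng.poisson(r * (tt - ii))
                intact[small] = rng.binomial(off_intact, 1.0 - theta)
                total[small] = off_intact + off_other
            big = ~small
            if np.any(big):
                new_tot = total[big] * r
                clip = np.minimum(1.0, 1e30 / new_tot)  # keeps I/N exact
                total[big] = new_tot * clip
                intact[big] = intact[big] * r * (1.0 - theta) * clip
        return intact, total

    I, N = run_block(n_reps)
    bad = np.flatnonzero(N < 1)
    rounds = 0
    while bad.size:
        rounds += 1
        if rounds > max_rounds:
            raise SimulationError(
                f"conditioning on survival failed after {max_rounds} "
                f"resampling rounds (r={r}, g={g})"
            )
        Ib, Nb = run_block(bad.size)
        I[bad], N[bad] = Ib, Nb
        bad = bad[Nb < 1]

    nn = np.minimum(n_sample, N).astype(np.int64)
    # exact hypergeometric sampling; binomial approximation once the
    # population dwarfs the sample
    big = N > DETERMINISTIC_ABOVE
    intact_draw = np.empty(n_reps, dtype=np.int64)
    if np.any(~big):
        Ii = I[~big].astype(np.int64)
        Ni = N[~big].astype(np.int64)
        intact_draw[~big] = rng.hypergeometric(Ii, Ni - Ii, nn[~big])
    if np.any(big):
        intact_draw[big] = rng.binomial(nn[big], I[big] / N[big])
    match = rng.binomial(nn - intact_draw, p_anc)
    return (intact_draw + match) / nn


# ---------------------------------------------------------------------------
# Convenience scene builders

def evenly_spaced_snp_map(
    n_markers: int,
    span_bp: int,
    cm_per_mb: float = 1.0,
    map_function: str = "haldane",
    mutation_rate: float | None = None,
) -> MarkerMap:
    """SNP markers evenly spanning ``span_bp`` with the disease locus midway
    between the two central markers."""
    positions = np.linspace(0, span_bp, n_markers).astype(np.int64)
    mid = n_markers // 2
    locus = int((positions[mid - 1] + positions[mid]) / 2)
    markers = [
        Marker(
            name=f"M{i + 1:02d}",
            position_bp=int(p),
            marker_type="snp",
            alleles=("A", "B"),
            mutation_rate_per_gen=mutation_rate,
        )
        for i, p in enumerate(positions)
    ]
    return build_marker_map(markers, locus, cm_per_mb, map_function)


def random_snp_pool(
    mmap: MarkerMap,
    rng: np.random.Generator,
    maf_range: tuple[float, float] = (0.2, 0.8),
) -> BackgroundPool:
    """Linkage-equilibrium pool with per-marker allele frequencies drawn
    uniformly from ``maf_range`` (first allele)."""
    freqs = []
    for _m in mmap.markers:
        p = rng.uniform(*maf_range)
        freqs.append(np.array([p, 1.0 - p]))
    return BackgroundPool.from_site_frequencies(freqs)


# ---------------------------------------------------------------------------
# Dataset round trip (TSV haplotypes/genotypes, YAML config, JSON truth)

def write_dataset(dataset: CaseControlDataset, truth: SimTruth | None, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmap = dataset.marker_map
    write_marker_map_tsv(mmap, outdir / "map.tsv")
    with open(outdir / "dataset.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "disease_locus_bp": int(mmap.disease_locus_bp),
                "cm_per_mb": float(mmap.cm_per_mb),
                "map_function": mmap.map_function,
            },
            fh,
        )

    names = mmap.names
    with open(outdir / "haplotypes.tsv", "w") as fh:
        fh.write(
            "sample_id\tchrom_index\tcarrier_flag\tprobability\t"
            + "\t".join(names)
            + "\n"
        )
        for d in dataset.carriers:
            for hap, p in d.entries:
                fh.write(
                    f"{d.sample_id}\t1\t1\t{p:.12g}\t" + "\t".join(hap) + "\n"
                )
        for sid, hap in zip(dataset.control_ids, dataset.control_haplotypes):
            base, _, chrom = sid.partition("/")
            fh.write(f"{base}\t{chrom or 1}\t0\t1\t" + "\t".join(hap) + "\n")

    if dataset.genotypes is not None:
        carrier_ids = {d.sample_id for d in dataset.carriers}
        with open(outdir / "genotypes.tsv", "w") as fh:
            fh.write("sample_id\tcarrier_flag\t" + "\t".join(names) + "\n")
            for sid, geno in dataset.genotypes.items():
                flag = 1 if sid in carrier_ids else 0
                fh.write(
                    f"{sid}\t{flag}\t"
                    + "\t".join(f"{a}/{b}" for a, b in geno)
                    + "\n"
                )

    if truth is not None:
        payload = {
            "g_true": truth.g_true,
            "r": truth.r,
            "genealogy": truth.genealogy,
            "ancestral_alleles": list(truth.ancestral_alleles),
            "lineage_count_trajectory": truth.lineage_count_trajectory,
            "intact_proximal": (
                None
                if truth.intact_proximal is None
                else truth.intact_proximal.tolist()
            ),
            "intact_distal": (
                None if truth.intact_distal is None else truth.intact_distal.tolist()
            ),
            "mutation_counts": (
                None
                if truth.mutation_counts is None
                else truth.mutation_counts.tolist()
            ),
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(payload, fh, indent=1)


class DatasetParseError(ValueError):
    """Malformed dataset file; message carries the file and line number."""


def read_dataset(outdir):
    """Read a dataset directory written by :func:`write_dataset`.

    Returns ``(CaseControlDataset, SimTruth | None)``.
    """
    from pathlib import Path

    outdir = Path(outdir)
    with open(outdir / "dataset.yaml") as fh:
        meta = yaml.safe_load(fh)
    mmap = read_marker_map_tsv(
        outdir / "map.tsv",
        disease_locus_bp=int(meta["disease_locus_bp"]),
        cm_per_mb=float(meta["cm_per_mb"]),
        map_function=meta.get("map_function", "haldane"),
    )
    names = mmap.names
    valid = [set(m.alleles) for m in mmap.markers]

    carrier_entries: dict[str, list] = {}
    control_haps: list[tuple[str, ...]] = []
    control_ids: list[str] = []
    path = outdir / "haplotypes.tsv"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "chrom_index", "carrier_flag", "probability"] + list(
            names
        )
        if header != expected:
            raise DatasetParseError(f"{path}:1: header does not match map")
        for lineno, raw in enumerate(fh, 2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 4 + len(names):
                raise DatasetParseError(f"{path}:{lineno}: wrong column count")
            sid, chrom, flag, prob = parts[:4]
            hap = tuple(parts[4:])
            for j, a in enumerate(hap):
                if a not in valid[j]:
                    raise DatasetParseError(
                        f"{path}:{lineno}: allele {a!r} not in map for marker "
                        f"{names[j]}"
                    )
            try:
                p = float(prob)
            except ValueError:
                raise DatasetParseError(
                    f"{path}:{lineno}: bad probability {prob!r}"
                ) from None
            if flag == "1":
                carrier_entries.setdefault(sid, []).append((hap, p))
            else:
                control_haps.append(hap)
                control_ids.append(f"{sid}/{chrom}")

    carriers = [
        HaplotypeDistribution.from_weighted(sid, entries, prune=0.0)
        for sid, entries in carrier_entries.items()
    ]

    genotypes = None
    geno_flags = None
    gpath = outdir / "genotypes.tsv"
    if gpath.exists():
        genotypes = {}
        geno_flags = {}
        with open(gpath) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["sample_id", "carrier_flag"] + list(names):
                raise DatasetParseError(f"{gpath}:1: header does not match map")
            for lineno, raw in enumerate(fh, 2):
                if not raw.strip():
                    continue
                parts = raw.rstrip("\n").split("\t")
                sid = parts[0]
                pairs = []
                for j, cell in enumerate(parts[2:]):
                    a, sep, b = cell.partition("/")
                    if not sep:
                        raise DatasetParseError(
                            f"{gpath}:{lineno}: bad genotype {cell!r}"
                        )
                    if a not in valid[j] or b not in valid[j]:
                        raise DatasetParseError(
                            f"{gpath}:{lineno}: allele not in map for marker "
                            f"{names[j]}"
                        )
                    pairs.append(tuple(sorted((a, b))))
                genotypes[sid] = pairs
                geno_flags[sid] = 1 if parts[1] == "1" else 0

    dataset = CaseControlDataset(
        marker_map=mmap,
        carriers=carriers,
        control_haplotypes=control_haps,
        control_ids=control_ids,
        genotypes=genotypes,
        genotype_carrier_flags=geno_flags,
    )

    truth = None
    tpath = outdir / "truth.json"
    if tpath.exists():
        with open(tpath) as fh:
            payload = json.load(fh)
        truth = SimTruth(
            g_true=payload["g_true"],
            r=payload["r"],
            genealogy=payload["genealogy"],
            ancestral_alleles=tuple(payload["ancestral_alleles"]),
            lineage_count_trajectory=payload["lineage_count_trajectory"],
            intact_proximal=(
                None
                if payload["intact_proximal"] is None
                else np.asarray(payload["intact_proximal"])
            ),
            intact_distal=(
                None
                if payload["intact_distal"] is None
                else np.asarray(payload["intact_distal"])
            ),
            mutation_counts=(
                None
                if payload["mutation_counts"] is None
                else np.asarray(payload["mutation_counts"])
            ),
        )
    return dataset, truth
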