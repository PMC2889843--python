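"""Carrier haplotype distributions, allele frequencies, ancestral inference.

The multi-marker likelihood needs, for each known mutation carrier, a
distribution over the marker haplotypes that could be riding with the
mutation. With phased input this is a point mass; with unphased genotypes it
comes from a phasing program. Two sources are supported: the pair-listing
output dialect of PHASE v2, and a built-in enumeration EM phaser suitable for
windows of up to ~12 markers. The mutation site itself is treated as an
anchor column identifying the carrier chromosome, not as a map marker.

Population ("normal") allele frequencies p_N are estimated by direct allele
counting in control chromosomes; carrier ("disease") frequencies p_D by
probability-weighted counting over the carrier haplotype distributions. The
ancestral (mutation-associated) allele at each marker is the
probability-weighted mode across carriers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .genmap import MarkerMap

#: entries below this probability are pruned after merging, then renormalized
PRUNE_THRESHOLD = 1e-6


class HaplotypeError(ValueError):
    """Invalid haplotype-distribution input."""


@dataclass
class HaplotypeDistribution:
    """Per-carrier candidate mutation-bearing haplotypes with probabilities."""

    sample_id: str
    entries: list[tuple[tuple[str, ...], float]]

    def __post_init__(self):
        if not self.entries:
            raise HaplotypeError(f"{self.sample_id}: empty distribution")
        lengths = {len(h) for h, _ in self.entries}
        if len(lengths) != 1:
            raise HaplotypeError(f"{self.sample_id}: unequal haplotype lengths")
        total = sum(p for _, p in self.entries)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise HaplotypeError(
                f"{self.sample_id}: probabilities sum to {total}, not 1"
            )
        if any(p <= 0 for _, p in self.entries):
            raise HaplotypeError(f"{self.sample_id}: non-positive probability")

    @classmethod
    def certain(cls, sample_id: str, hap) -> "HaplotypeDistribution":
        return cls(sample_id, [(tuple(str(a) for a in hap), 1.0)])

    @classmethod
    def from_weighted(
        cls, sample_id: str, weighted, prune: float = PRUNE_THRESHOLD
    ) -> "HaplotypeDistribution":
        """Merge duplicate haplotypes, prune tiny entries, renormalize."""
        acc: dict[tuple[str, ...], float] = {}
        for hap, w in weighted:
            hap = tuple(str(a) for a in hap)
            acc[hap] = acc.get(hap, 0.0) + float(w)
        total = sum(acc.values())
        if total <= 0:
            raise HaplotypeError(f"{sample_id}: zero total probability")
        kept = {h: w / total for h, w in acc.items() if w / total >= prune}
        if not kept:
            raise HaplotypeError(f"{sample_id}: all entries pruned")
        norm = sum(kept.values())
        entries = [(h, w / norm) for h, w in sorted(kept.items())]
        return cls(sample_id, entries)

    @property
    def n_markers(self) -> int:
        return len(self.entries[0][0])

    def map_probability(self) -> tuple[tuple[str, ...], float]:
        """Most probable haplotype and its probability."""
        return max(self.entries, key=lambda e: e[1])


@dataclass
class AlleleFrequencies:
    """Per-marker allele frequencies in controls (p_N) and carriers (p_D)."""

    control: list[dict[str, float]]
    carrier: list[dict[str, float]]

    def __post_init__(self):
        for table in (self.control, self.carrier):
            for i, freqs in enumerate(table):
                total = sum(freqs.values())
                if not math.isclose(total, 1.0, abs_tol=1e-9):
                    raise HaplotypeError(
                        f"marker {i}: frequencies sum to {total}, not 1"
                    )

    @property
    def n_markers(self) -> int:
        return len(self.control)

    def p_N(self, i: int, allele: str) -> float:
        try:
            return self.control[i][str(allele)]
        except KeyError:
            raise HaplotypeError(
                f"allele {allele!r} absent from control frequency table at marker {i}"
            ) from None

    def p_D(self, i: int, allele: str) -> float:
        return self.carrier[i].get(str(allele), 0.0)


@dataclass
class AncestralHaplotype:
    """Mutation-associated allele per marker with its weighted support."""

    alleles: tuple[str, ...]
    support: np.ndarray

    def __len__(self) -> int:
        return len(self.alleles)


def allele_frequencies(
    control_haplotypes,
    carrier_distributions: list[HaplotypeDistribution],
    marker_map: MarkerMap | None = None,
) -> AlleleFrequencies:
    """Count control alleles directly and carrier alleles probability-weighted.

    When a marker map is given, every map allele appears in the tables (with
    frequency 0 if unobserved), so downstream lookups never miss.
    """
    controls = [tuple(str(a) for a in h) for h in control_haplotypes]
    if not controls:
        raise HaplotypeError("no control chromosomes")
    n_markers = len(controls[0])
    if any(len(h) != n_markers for h in controls):
        raise HaplotypeError("unequal control haplotype lengths")
    if carrier_distributions and carrier_distributions[0].n_markers != n_markers:
        raise HaplotypeError("carrier/control marker-count mismatch")

    def base_table(i):
        if marker_map is not None:
            return {a: 0.0 for a in marker_map.markers[i].alleles}
        return {}

    control_tab = []
    for i in range(n_markers):
        counts = base_table(i)
        for h in controls:
            counts[h[i]] = counts.get(h[i], 0.0) + 1.0
        control_tab.append({a: c / len(controls) for a, c in counts.items()})

    carrier_tab = []
    total_w = sum(
        p for d in carrier_distributions for _, p in d.entries
    )  # == number of carriers
    for i in range(n_markers):
        counts = base_table(i)
        for d in carrier_distributions:
            for hap, p in d.entries:
                counts[hap[i]] = counts.get(hap[i], 0.0) + p
        if total_w > 0:
            carrier_tab.append({a: c / total_w for a, c in counts.items()})
        else:
            carrier_tab.append(control_tab[i])
    return AlleleFrequencies(control=control_tab, carrier=carrier_tab)


def infer_ancestral_haplotype(
    distributions: list[HaplotypeDistribution],
    controls: AlleleFrequencies | None = None,
) -> AncestralHaplotype:
    """Weighted-mode ancestral allele per marker across carrier distributions.

    Ties go to the allele most enriched in carriers relative to controls
    (largest p_D/p_N) when control frequencies are available, then to the
    lexicographically smallest label.
    """
    if not distributions:
        raise HaplotypeError("no carrier distributions")
    n_markers = distributions[0].n_markers
    alleles = []
    support = np.empty(n_markers)
    total = float(len(distributions))
    for i in range(n_markers):
        counts: dict[str, float] = {}
        for d in distributions:
            for hap, p in d.entries:
                counts[hap[i]] = counts.get(hap[i], 0.0) + p

        w_max = max(counts.values())
        tied = [a for a, w in counts.items() if w == w_max]
        if len(tied) > 1 and controls is not None:

            def ratio(a):
                pn = controls.control[i].get(a, 0.0)
                pd = controls.carrier[i].get(a, 0.0)
                return math.inf if pn == 0 else pd / pn

            r_max = max(ratio(a) for a in tied)
            tied = [a for a in tied if ratio(a) == r_max]
        best = min(tied)
        alleles.append(best)
        support[i] = w_max / total
    return AncestralHaplotype(alleles=tuple(alleles), support=support)


# ---------------------------------------------------------------------------
# Enumeration EM phaser (PHASE stand-in for small windows)

MAX_EM_MARKERS = 12


def _compatible_pairs(genotype):
    """All ordered-canonical haplotype pairs compatible with one genotype.

    ``genotype`` is a sequence of unordered allele pairs. Enumeration fixes
    the first heterozygous marker's orientation, yielding 2**(h-1) pairs.
    """
    het = [i for i, (a, b) in enumerate(genotype) if a != b]
    pairs = []
    for bits in itertools.product((0, 1), repeat=max(len(het) - 1, 0)):
        orient = {het[0]: 0} if het else {}
        for j, bit in zip(het[1:], bits):
            orient[j] = bit
        h1, h2 = [], []
        for i, (a, b) in enumerate(genotype):
            if a == b:
                h1.append(a)
                h2.append(a)
            elif orient[i] == 0:
                h1.append(a)
                h2.append(b)
            else:
                h1.append(b)
                h2.append(a)
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def em_haplotype_frequencies(
    genotypes: dict,
    max_iter: int = 500,
    tol: float = 1e-8,
):
    """EM estimate of haplotype frequencies from unphased genotypes.

    ``genotypes`` maps sample_id to a sequence of unordered allele pairs
    (one 2-tuple per marker). Initialization is uniform over all compatible
    haplotypes and the run is deterministic. Returns
    ``(frequencies, phase_distributions, info)`` where ``phase_distributions``
    maps sample_id to a list of ``((hap1, hap2), probability)`` and ``info``
    records iterations and the log-likelihood trace (asserted non-decreasing).
    """
    if not genotypes:
        raise HaplotypeError("no individuals to phase")
    n_markers = {len(g) for g in genotypes.values()}
    if len(n_markers) != 1:
        raise HaplotypeError("unequal genotype lengths")
    (m,) = n_markers
    if m > MAX_EM_MARKERS:
        raise HaplotypeError(
            f"{m} markers exceeds the {MAX_EM_MARKERS}-marker enumeration window; "
            "phase in smaller windows"
        )

    sample_pairs = {}
    hap_index: dict[tuple, int] = {}
    for sid, geno in genotypes.items():
        geno = [tuple(sorted((str(a), str(b)))) for a, b in geno]
        pairs = _compatible_pairs(geno)
        idx_pairs = []
        for h1, h2 in pairs:
            for h in (h1, h2):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
            idx_pairs.append((hap_index[h1], hap_index[h2]))
        sample_pairs[sid] = idx_pairs

    haps = list(hap_index)
    K = len(haps)
    f = np.full(K, 1.0 / K)
    n = len(sample_pairs)
    loglik_trace = []
    prev_ll = -np.inf
    for it in range(max_iter):
        counts = np.zeros(K)
        ll = 0.0
        for idx_pairs in sample_pairs.values():
            w = np.array(
                [f[i] * f[j] * (2.0 if i != j else 1.0) for i, j in idx_pairs]
            )
            tot = w.sum()
            ll += math.log(tot)
            w /= tot
            for (i, j), wk in zip(idx_pairs, w):
                counts[i] += wk
                counts[j] += wk
        if ll < prev_ll - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        loglik_trace.append(ll)
        new_f = counts / (2.0 * n)
        delta = np.max(np.abs(new_f - f))
        f = new_f
        if delta < tol and it > 0:
            break
        prev_ll = ll

    freqs = {haps[k]: float(f[k]) for k in range(K) if f[k] > 0}
    phase = {}
    for sid, idx_pairs in sample_pairs.items():
        w = np.array([f[i] * f[j] * (2.0 if i != j else 1.0) for i, j in idx_pairs])
        w = w / w.sum()
        phase[sid] = [
            ((haps[i], haps[j]), float(wk))
            for (i, j), wk in zip(idx_pairs, w)
            if wk > 0
        ]
    info = {"n_iter": len(loglik_trace), "loglik": loglik_trace}
    return freqs, phase, info


def carrier_haplotype_distribution(
    sample_id: str,
    phase_distribution,
    carrier: bool = True,
    anchor_index: int | None = None,
    mutant_allele: str = "1",
    prune: float = PRUNE_THRESHOLD,
) -> HaplotypeDistribution:
    """Distribution over the mutation-bearing chromosome's marker haplotype.

    ``phase_distribution`` is a list of ``((hap1, hap2), probability)``. When
    ``anchor_index`` is given, the haplotypes include an anchor column at that
    index whose ``mutant_allele`` marks the carrier chromosome (stripped from
    the output); a homozygous-carrier configuration contributes both
    chromosomes at half weight. Without an anchor, hap1 is taken to be the
    carrier chromosome by convention.
    """
    if not carrier:
        raise HaplotypeError(f"{sample_id}: not flagged as a mutation carrier")
    if not phase_distribution:
        raise HaplotypeError(f"{sample_id}: empty phase distribution")
    weighted = []
    for (h1, h2), p in phase_distribution:
        if anchor_index is None:
            weighted.append((tuple(h1), p))
            continue
        bearing = [
            h for h in (h1, h2) if str(h[anchor_index]) == str(mutant_allele)
        ]
        if not bearing:
            continue
        share = p / len(bearing)
        for h in bearing:
            stripped = tuple(a for k, a in enumerate(h) if k != anchor_index)
            weighted.append((stripped, share))
    if not weighted:
        raise HaplotypeError(
            f"{sample_id}: no phase configuration carries the mutant anchor allele"
        )
    return HaplotypeDistribution.from_weighted(sample_id, weighted, prune=prune)


# ---------------------------------------------------------------------------
# Interchange formats

def read_phase_pairs(path) -> dict[str, list]:
    """Read a PHASE v2 pair-listing file into phase distributions.

    Expected dialect::

        IND: sample1
        1 0 1 , 1 1 1 , 0.85
        1 1 1 , 1 0 1 , 0.15

    Probabilities for each individual are renormalized to sum to 1.
    """
    out: dict[str, list] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("BEGIN", "END")):
                continue
            if line.startswith("IND:"):
                current = line[4:].strip()
                out[current] = []
                continue
            if current is None:
                raise HaplotypeError(f"{path}:{lineno}: pair line before IND:")
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 3:
                raise HaplotypeError(
                    f"{path}:{lineno}: expected 'hap1 , hap2 , prob'"
                )
            h1 = tuple(parts[0].split())
            h2 = tuple(parts[1].split())
            try:
                p = float(parts[2])
            except ValueError:
                raise HaplotypeError(f"{path}:{lineno}: bad probability") from None
            if len(h1) != len(h2):
                raise HaplotypeError(f"{path}:{lineno}: unequal haplotype lengths")
            out[current].append(((h1, h2), p))
    for sid, pairs in out.items():
        total = sum(p for _, p in pairs)
        if total <= 0:
            raise HaplotypeError(f"{path}: {sid}: zero total probability")
        out[sid] = [(hp, p / total) for hp, p in pairs]
    return out


def write_pairs_tsv(phase: dict[str, list], path) -> None:
    """Native interchange: sample_id, hap1, hap2, probability (alleles comma-joined)."""
    with open(path, "w") as fh:
        fh.write("sample_id\thap1\thap2\tprobability\n")
        for sid, pairs in phase.items():
            for (h1, h2), p in pairs:
                fh.write(f"{sid}\t{','.join(h1)}\t{','.join(h2)}\t{p:.12g}\n")


def read_pairs_tsv(path) -> dict[str, list]:
    out: dict[str, list] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sample_id", "hap1", "hap2", "probability"]:
            raise HaplotypeError(f"{path}:1: bad header {header}")
        for lineno, raw in enumerate(fh, 2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise HaplotypeError(f"{path}:{lineno}: expected 4 columns")
            sid, h1, h2, p = parts
            try:
                prob = float(p)
            except ValueError:
                raise HaplotypeError(f"{path}:{lineno}: bad probability") from None
            out.setdefault(sid, []).append(
                ((tuple(h1.split(",")), tuple(h2.split(","))), prob)
            )
    for sid, pairs in out.items():
        total = sum(p for _, p in pairs)
        out[sid] = [(hp, p / total) for hp, p in pairs]
    return out
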