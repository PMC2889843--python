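"""Marker maps: physical positions, genetic distance, recombination fractions.

A :class:`MarkerMap` orders markers along a chromosome around a known disease
locus and carries two recombination-fraction views of the same geometry:

* ``theta_to_locus`` -- the fraction between each marker and the disease locus
  (what the single-marker LD-decay estimator consumes);
* ``theta_interval`` -- the fraction between each marker and its inward
  neighbour (the locus itself for the innermost marker on each side), which is
  what the outward multi-marker likelihood scan consumes.

Physical distance is converted to genetic distance with a constant cM/Mb rate
(default 1.0), and genetic distance to a recombination fraction with the
Haldane map function by default (a linear no-interference approximation is
available; at the sub-10-cM scales typical of founder-mutation maps the two
nearly coincide).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MARKER_TYPES = ("snp", "dinucleotide_str", "tetranucleotide_str", "other")

#: Per-generation marker mutation rates by marker type, overridable per marker.
DEFAULT_MUTATION_RATES = {
    "snp": 1e-8,
    "dinucleotide_str": 5e-4,
    "tetranucleotide_str": 2e-4,
    "other": 1e-5,
}

MAP_FUNCTIONS = ("haldane", "linear")


class GenmapError(ValueError):
    """Invalid marker or map construction input."""


def _str_sort_key(label: str):
    try:
        return (0, float(label))
    except ValueError:
        return (1, label)


@dataclass(frozen=True)
class Marker:
    """A polymorphic marker at a point position.

    For short-tandem-repeat types the allele list is sorted numerically at
    construction so that it defines the stepwise-mutation chain; SNP and
    "other" alleles keep their given order.
    """

    name: str
    position_bp: int
    marker_type: str = "snp"
    alleles: tuple[str, ...] = ("0", "1")
    mutation_rate_per_gen: float | None = None

    def __post_init__(self):
        if self.position_bp < 0:
            raise GenmapError(f"marker {self.name}: negative position")
        if self.marker_type not in MARKER_TYPES:
            raise GenmapError(
                f"marker {self.name}: unknown type {self.marker_type!r}"
            )
        alleles = tuple(str(a) for a in self.alleles)
        if len(alleles) < 2:
            raise GenmapError(f"marker {self.name}: needs >= 2 alleles")
        if len(set(alleles)) != len(alleles):
            raise GenmapError(f"marker {self.name}: duplicate allele labels")
        if self.marker_type.endswith("_str"):
            alleles = tuple(sorted(alleles, key=_str_sort_key))
        object.__setattr__(self, "alleles", alleles)
        if self.mutation_rate_per_gen is not None and not (
            0.0 <= self.mutation_rate_per_gen <= 1.0
        ):
            raise GenmapError(f"marker {self.name}: mutation rate outside [0,1]")

    @property
    def mutation_rate(self) -> float:
        """Per-generation mutation rate: explicit override or type default."""
        if self.mutation_rate_per_gen is not None:
            return self.mutation_rate_per_gen
        return DEFAULT_MUTATION_RATES[self.marker_type]

    def allele_index(self, label: str) -> int:
        try:
            return self.alleles.index(str(label))
        except ValueError:
            raise GenmapError(
                f"allele {label!r} not in marker {self.name} alleles {self.alleles}"
            ) from None


def cm_from_physical(distance_bp: float, cm_per_mb: float = 1.0) -> float:
    """Convert physical distance (bp) to genetic distance (cM)."""
    if distance_bp < 0:
        raise GenmapError("distance_bp must be >= 0")
    if cm_per_mb <= 0:
        raise GenmapError("cm_per_mb must be > 0")
    return distance_bp * cm_per_mb / 1e6


def theta_from_cm(d_cm, map_function: str = "haldane"):
    """Recombination fraction from genetic distance in cM.

    Haldane (no interference): theta = (1 - exp(-2 d_Morgan)) / 2, in [0, 0.5).
    Linear: theta = d_Morgan capped at 0.5.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise GenmapError("genetic distance must be >= 0")
    if map_function == "haldane":
        theta = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    elif map_function == "linear":
        theta = np.minimum(d / 100.0, 0.5)
    else:
        raise GenmapError(f"unknown map function {map_function!r}")
    return float(theta) if np.isscalar(d_cm) else theta


@dataclass(frozen=True)
class MarkerMap:
    """Position-ordered markers around a disease locus.

    ``proximal_order`` / ``distal_order`` list marker indices inside-out
    (nearest the locus first) for the two flanks; ``theta_interval[i]`` is the
    recombination fraction between marker i and its inward neighbour on its
    own flank.
    """

    markers: tuple[Marker, ...]
    disease_locus_bp: int
    cm_per_mb: float
    map_function: str
    theta_to_locus: np.ndarray
    theta_interval: np.ndarray
    proximal_order: tuple[int, ...]
    distal_order: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def distance_to_locus_bp(self, i: int) -> int:
        return abs(self.markers[i].position_bp - self.disease_locus_bp)

    def side_orders(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        return self.proximal_order, self.distal_order


def build_marker_map(
    markers,
    disease_locus_bp: int,
    cm_per_mb: float = 1.0,
    map_function: str = "haldane",
    interval_theta_override: dict[str, float] | None = None,
) -> MarkerMap:
    """Build a :class:`MarkerMap`; markers may be given in any order.

    ``interval_theta_override`` maps a marker name to the recombination
    fraction for its *inward* interval, replacing the distance-derived value
    (for users with an empirical per-interval estimate).
    """
    markers = tuple(sorted(markers, key=lambda m: m.position_bp))
    if not markers:
        raise GenmapError("marker list is empty")
    positions = [m.position_bp for m in markers]
    if len(set(positions)) != len(positions):
        raise GenmapError("duplicate marker positions")
    if any(p == disease_locus_bp for p in positions):
        raise GenmapError("a marker coincides with the disease locus position")
    if map_function not in MAP_FUNCTIONS:
        raise GenmapError(f"unknown map function {map_function!r}")

    n = len(markers)
    theta_to_locus = np.empty(n)
    for i, m in enumerate(markers):
        d = cm_from_physical(abs(m.position_bp - disease_locus_bp), cm_per_mb)
        theta_to_locus[i] = theta_from_cm(d, map_function)

    # proximal markers sorted descending by position == nearest-first
    proximal = tuple(
        sorted(
            (i for i in range(n) if markers[i].position_bp < disease_locus_bp),
            key=lambda i: -markers[i].position_bp,
        )
    )
    distal = tuple(
        sorted(
            (i for i in range(n) if markers[i].position_bp > disease_locus_bp),
            key=lambda i: markers[i].position_bp,
        )
    )

    theta_interval = np.empty(n)
    for order in (proximal, distal):
        prev_bp = disease_locus_bp
        for i in order:
            d = cm_from_physical(abs(markers[i].position_bp - prev_bp), cm_per_mb)
            theta_interval[i] = theta_from_cm(d, map_function)
            prev_bp = markers[i].position_bp
    if interval_theta_override:
        names = [m.name for m in markers]
        for name, th in interval_theta_override.items():
            if name not in names:
                raise GenmapError(f"override for unknown marker {name!r}")
            if not (0.0 <= th <= 0.5):
                raise GenmapError("theta override outside [0, 0.5]")
            theta_interval[names.index(name)] = th

    return MarkerMap(
        markers=markers,
        disease_locus_bp=disease_locus_bp,
        cm_per_mb=cm_per_mb,
        map_function=map_function,
        theta_to_locus=theta_to_locus,
        theta_interval=theta_interval,
        proximal_order=proximal,
        distal_order=distal,
    )


# ---------------------------------------------------------------------------
# TSV interchange: name, chrom, position_bp, type, alleles, mutation_rate

def write_marker_map_tsv(mmap: MarkerMap, path, chrom: str = "NA") -> None:
    rows = []
    for m in mmap.markers:
        rows.append(
            {
                "name": m.name,
                "chrom": chrom,
                "position_bp": m.position_bp,
                "type": m.marker_type,
                "alleles": ",".join(m.alleles),
                "mutation_rate": (
                    "" if m.mutation_rate_per_gen is None else m.mutation_rate_per_gen
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_marker_map_tsv(
    path,
    disease_locus_bp: int,
    cm_per_mb: float = 1.0,
    map_function: str = "haldane",
) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"alleles": str})
    required = {"name", "chrom", "position_bp", "type", "alleles"}
    missing = required - set(df.columns)
    if missing:
        raise GenmapError(f"marker map TSV missing columns: {sorted(missing)}")
    markers = []
    for _, row in df.iterrows():
        rate = None
        if "mutation_rate" in df.columns and pd.notna(row.get("mutation_rate")):
            val = row["mutation_rate"]
            if not (isinstance(val, str) and val.strip() == ""):
                rate = float(val)
        markers.append(
            Marker(
                name=str(row["name"]),
                position_bp=int(row["position_bp"]),
                marker_type=str(row["type"]),
                alleles=tuple(str(row["alleles"]).split(",")),
                mutation_rate_per_gen=rate,
            )
        )
    return build_marker_map(markers, disease_locus_bp, cm_per_mb, map_function)
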