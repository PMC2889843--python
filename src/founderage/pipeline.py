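"""Configuration-driven end-to-end runs: simulate/load, phase, estimate, report.

A :class:`RunConfig` (typically read from YAML) describes one reproducible
run: where the data comes from (a simulation block or a dataset directory),
which estimators to run, which growth rates to evaluate, and how to correct
for growth. ``run`` executes the enabled stages in order, writes every
artifact (per-marker TSV, likelihood curve, report JSON/TSV, the config
echo) into the output directory, and returns the report table. All
randomness flows from the single configured seed, so a rerun with the same
config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import goldgar, single_marker
from .genmap import read_marker_map_tsv
from .haplotypes import (
    allele_frequencies,
    carrier_haplotype_distribution,
    em_haplotype_frequencies,
    infer_ancestral_haplotype,
)
from .synthetic_data import (
    CaseControlDataset,
    SimConfig,
    evenly_spaced_snp_map,
    random_snp_pool,
    read_dataset,
    simulate_dataset,
    write_dataset,
)

log = logging.getLogger("founderage")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def interval_width(low: float, high: float) -> float:
    """Interval width rounded to one decimal (reporting convention)."""
    if high < low:
        raise PipelineError(f"report: interval high {high} < low {low}")
    return round(high - low, 1)


@dataclass
class SimulateBlock:
    """Simulation scene: an evenly spaced SNP map with an LE background pool."""

    g_true: int = 17
    r: float = 1.5
    n_cases: int = 16
    n_controls: int = 109
    n_markers: int = 19
    span_bp: int = 12_300_000
    cm_per_mb: float = 1.0
    genealogy: str = "branching"
    maf_range: tuple[float, float] = (0.2, 0.8)
    map_tsv: str | None = None
    disease_locus_bp: int | None = None


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "founderage_out"
    simulate: SimulateBlock | None = None
    input_dir: str | None = None
    methods: tuple[str, ...] = ("single_marker", "goldgar")
    growth_rates: tuple[float, ...] = (1.5,)
    correction_mode: str | None = "montecarlo"  # None, "montecarlo", "table"
    correction_table: dict | None = None  # growth rate -> additive correction
    grid: tuple[int, int] = (0, 200)
    ci_cutoff: float = goldgar.CI_CUTOFF_95
    mc_reps: int = 1000
    years_per_generation: float = 25.0
    reference_year: float | None = None

    def __post_init__(self):
        if not self.methods:
            raise PipelineError("config: at least one method must be enabled")
        if self.correction_mode is not None and any(
            r <= 1.0 for r in self.growth_rates
        ):
            raise PipelineError(
                "config: growth rates must exceed 1 when a correction is requested"
            )
        if self.simulate is None and self.input_dir is None:
            raise PipelineError("config: need a simulation block or an input_dir")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(
            **{
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in raw.items()
            },
            simulate=SimulateBlock(
                **{
                    k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in sim.items()
                }
            )
            if sim is not None
            else None,
        )
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunResult:
    report: pd.DataFrame
    out_dir: Path
    estimates: dict


def _stage_data(config: RunConfig, rng: np.random.Generator):
    if config.input_dir is not None:
        dataset, truth = read_dataset(config.input_dir)
        log.info("loaded dataset from %s", config.input_dir)
        return dataset, truth
    blk = config.simulate
    if blk.map_tsv is not None:
        mmap = read_marker_map_tsv(
            blk.map_tsv,
            disease_locus_bp=blk.disease_locus_bp,
            cm_per_mb=blk.cm_per_mb,
        )
    else:
        mmap = evenly_spaced_snp_map(blk.n_markers, blk.span_bp, blk.cm_per_mb)
    pool = random_snp_pool(mmap, rng, blk.maf_range)
    sim = SimConfig(
        g_true=blk.g_true,
        r=blk.r,
        n_cases=blk.n_cases,
        n_controls=blk.n_controls,
        marker_map=mmap,
        background_pool=pool,
        seed=int(rng.integers(2**31)),
        genealogy=blk.genealogy,
    )
    dataset, truth = simulate_dataset(sim)
    log.info(
        "simulated dataset: g_true=%d r=%g %d cases, %d controls, %d markers",
        blk.g_true, blk.r, blk.n_cases, blk.n_controls, len(mmap),
    )
    return dataset, truth


def _stage_phase(dataset: CaseControlDataset):
    """Phase unphased carrier genotypes with the EM phaser when the carriers
    have no haplotype distributions yet; phased input passes through.

    Cases and controls are phased jointly (flagged assumption), with the
    mutation site appended as an anchor column that is heterozygous in
    carriers; the anchor identifies the mutation-bearing chromosome and is
    stripped from the resulting distributions.
    """
    if dataset.carriers:
        log.info("phasing skipped: carrier haplotype distributions present")
        return dataset
    if dataset.genotypes is None or dataset.genotype_carrier_flags is None:
        raise PipelineError("phase: no carrier haplotypes and no genotypes")
    log.info("phasing cases and controls jointly (assumption flagged)")
    m = len(dataset.marker_map)
    anchored = {}
    for sid, pairs in dataset.genotypes.items():
        flag = dataset.genotype_carrier_flags.get(sid, 0)
        anchor = ("0", "__mut__") if flag else ("0", "0")
        anchored[sid] = list(pairs) + [anchor]
    try:
        _freqs, phase, info = em_haplotype_frequencies(anchored)
    except Exception as exc:
        raise PipelineError(f"phase: {exc}") from exc
    log.info("EM phaser converged in %d iterations", info["n_iter"])
    carriers = [
        carrier_haplotype_distribution(
            sid, phase[sid], carrier=True, anchor_index=m, mutant_allele="__mut__"
        )
        for sid, flag in dataset.genotype_carrier_flags.items()
        if flag
    ]
    dataset.carriers = carriers
    return dataset


def _growth_correction(
    config: RunConfig,
    r: float,
    estimates: list[single_marker.SingleMarkerEstimate],
) -> float | None:
    """Median across-marker correction applied to the multi-marker estimate."""
    if config.correction_mode is None:
        return None
    if config.correction_mode == "table":
        table = config.correction_table or {}
        corr = table.get(r, table.get(float(r), table.get(str(r))))
        if corr is None:
            raise PipelineError(f"report: no table correction for r={r}")
        return float(corr)
    deltas = [
        e.correction
        for e in estimates
        if e.status == single_marker.STATUS_OK and e.correction is not None
    ]
    if not deltas:
        raise PipelineError(f"correction: no defined marker corrections at r={r}")
    import statistics

    return statistics.median(deltas)


def run(config: RunConfig) -> RunResult:
    """Execute the enabled stages and write all artifacts to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)

    try:
        dataset, truth = _stage_data(config, rng)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError(f"data: {exc}") from exc
    if config.simulate is not None:
        write_dataset(dataset, truth, out / "dataset")

    dataset = _stage_phase(dataset)

    try:
        freqs = allele_frequencies(
            dataset.control_haplotypes, dataset.carriers, dataset.marker_map
        )
        ancestral = infer_ancestral_haplotype(dataset.carriers, freqs)
    except Exception as exc:
        raise PipelineError(f"frequencies: {exc}") from exc
    log.info("inferred ancestral haplotype: %s", "".join(ancestral.alleles))

    rows = []
    estimates: dict = {}
    g_min, g_max = config.grid
    for r in config.growth_rates:
        try:
            sm = single_marker.estimate_markers(
                freqs,
                ancestral,
                dataset.marker_map,
                r=r if config.correction_mode == "montecarlo" else None,
                correction_mode=(
                    "montecarlo" if config.correction_mode == "montecarlo" else None
                ),
                n_sample=len(dataset.carriers),
                n_reps=config.mc_reps,
                seed=int(config.seed) + int(1000 * r),
            )
        except Exception as exc:
            raise PipelineError(f"single_marker: {exc}") from exc
        corr = _growth_correction(config, r, sm)
        if config.correction_mode == "table" and corr is not None:
            for e in sm:
                if e.status == single_marker.STATUS_OK and e.g_raw is not None:
                    e.correction = corr
                    e.g_corrected = e.g_raw + corr

        if "single_marker" in config.methods:
            summary = single_marker.summarize_markers(sm)
            log.info(
                "single-marker r=%g: median %.2f over %d markers (%d excluded)",
                r, summary.median_g_raw, summary.n_used, summary.n_excluded,
            )
            rows.append(
                {
                    "method": "single_marker_median",
                    "growth_rate": r,
                    "g_raw": round(summary.median_g_raw, 2),
                    "g_corrected": (
                        None
                        if summary.median_g_corrected is None
                        else round(summary.median_g_corrected, 2)
                    ),
                    "ci_low": None,
                    "ci_high": None,
                    "interval_width": None,
                }
            )
            estimates[("single_marker", r)] = sm

        if "goldgar" in config.methods:
            try:
                model = goldgar.GoldgarModel(dataset.marker_map, ancestral, freqs)
                est = goldgar.mle_age(
                    dataset.carriers, model, g_min, g_max, config.ci_cutoff
                )
            except Exception as exc:
                raise PipelineError(f"goldgar: {exc}") from exc
            if corr is not None:
                est = goldgar.corrected_age(est, corr)
            log.info(
                "goldgar r=%g: g_hat=%d CI %s flags=%s",
                r, est.g_hat, est.format_ci(), est.flags,
            )
            rows.append(
                {
                    "method": "goldgar",
                    "growth_rate": r,
                    "g_raw": est.g_hat,
                    "g_corrected": (
                        None if est.g_corrected is None else round(est.g_corrected, 2)
                    ),
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "interval_width": interval_width(est.ci_low, est.ci_high),
                }
            )
            estimates[("goldgar", r)] = est

    report = pd.DataFrame(rows)
    _write_artifacts(config, out, dataset, freqs, ancestral, estimates, report)
    return RunResult(report=report, out_dir=out, estimates=estimates)


def _write_artifacts(config, out, dataset, freqs, ancestral, estimates, report):
    mmap = dataset.marker_map
    for (kind, r), val in estimates.items():
        tag = f"{kind}_r{r:g}".replace(".", "_")
        if kind == "single_marker":
            rows = []
            for e in val:
                i = mmap.index_of(e.marker)
                rows.append(
                    {
                        "marker": e.marker,
                        "distance_bp": mmap.distance_to_locus_bp(i),
                        "theta": e.theta,
                        "p_D": e.p_D,
                        "p_N": e.p_N,
                        "delta": e.delta,
                        "g_raw": e.g_raw,
                        "correction": e.correction,
                        "g_corrected": e.g_corrected,
                        "status": e.status,
                    }
                )
            pd.DataFrame(rows).to_csv(out / f"{tag}.tsv", sep="\t", index=False)
        else:
            model = goldgar.GoldgarModel(mmap, ancestral, freqs)
            grid, ll = goldgar.loglik_curve(
                dataset.carriers, model, *config.grid
            )
            pd.DataFrame({"g": grid, "loglik": ll}).to_csv(
                out / f"{tag}_curve.tsv", sep="\t", index=False
            )
            with open(out / f"{tag}.json", "w") as fh:
                json.dump(
                    {
                        "method": val.method,
                        "g_hat": val.g_hat,
                        "ci": [val.ci_low, val.ci_high],
                        "loglik": val.loglik_at_max,
                        "delta": val.correction,
                        "corrected": val.g_corrected,
                        "ci_corrected": val.ci_corrected,
                        "flags": list(val.flags),
                    },
                    fh,
                    indent=1,
                )
    report.to_json(out / "report.json", orient="records", indent=1)
    report.to_csv(out / "report.tsv", sep="\t", index=False)
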