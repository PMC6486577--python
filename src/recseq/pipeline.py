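"""End-to-end orchestration: config validation, staged execution, reporting.

A run processes one experiment side: a single pre-selection library sample
plus one or more post-selection replicates.  Stages are
extract -> filter -> tally -> enrichment -> kappa -> aggregate, with
profile TSVs, a kappa table, and a versioned JSON report written to the
output directory.  Everything is deterministic for fixed inputs and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .enrich import (
    CountTable,
    EnrichmentProfile,
    aggregate,
    enrichment,
    tally,
    write_profile_tsv,
)
from .quality import KappaResult, classify, kappa, umi_stats
from .readio import DEFAULT_MAX_MISMATCHES, FilterReport, ReadLayout, extract_fastq
from .simlib import (
    LibrarySpec,
    SelectionModel,
    SimConfig,
    expected_enrichment,
    simulate_experiment,
)
from .targets import Side, TargetSite, resolve_site

logger = logging.getLogger("recseq")

REPORT_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for sample {sample!r}: {cause}")
        self.stage = stage
        self.sample = sample
        self.cause = cause


@dataclass(frozen=True)
class Sample:
    role: str  # "pre" | "post"
    replicate: str
    fastq: Path

    def __post_init__(self) -> None:
        if self.role not in ("pre", "post"):
            raise ConfigError(f"sample role must be pre|post, got {self.role!r}")


@dataclass
class RunConfig:
    site: TargetSite
    randomized_side: Side
    samples: list[Sample]
    umi_length: int = 10
    max_mismatches: int = DEFAULT_MAX_MISMATCHES
    pseudocount: float = 0.5
    motif_threshold: float = 2.0
    kappa_literal_orientation: bool = False
    out_dir: Path = Path("recseq-out")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, data: dict[str, Any], base_dir: Path = Path(".")) -> "RunConfig":
        try:
            site = resolve_site(data["site"])
            samples = [
                Sample(s["role"], str(s.get("replicate", i + 1)),
                       (base_dir / s["fastq"]).resolve())
                for i, s in enumerate(data["samples"])
            ]
        except KeyError as exc:
            raise ConfigError(f"missing config key: {exc}") from exc
        return cls(
            site=site,
            randomized_side=Side(data.get("randomized_side", "left")),
            samples=samples,
            umi_length=int(data.get("umi_length", 10)),
            max_mismatches=int(data.get("max_mismatches", DEFAULT_MAX_MISMATCHES)),
            pseudocount=float(data.get("pseudocount", 0.5)),
            motif_threshold=float(data.get("motif_threshold", 2.0)),
            kappa_literal_orientation=bool(data.get("kappa_literal_orientation", False)),
            out_dir=(base_dir / data.get("out_dir", "recseq-out")).resolve(),
            seed=int(data.get("seed", 0)),
        )

    def validate(self) -> None:
        pre = [s for s in self.samples if s.role == "pre"]
        post = [s for s in self.samples if s.role == "post"]
        if len(pre) != 1:
            raise ConfigError(
                f"exactly one pre-library sample required, found {len(pre)}"
            )
        if not post:
            raise ConfigError("at least one post-selection sample required")
        for s in self.samples:
            if not s.fastq.exists():
                raise ConfigError(f"FASTQ not found: {s.fastq}")

    @property
    def layout(self) -> ReadLayout:
        return ReadLayout(self.site, self.randomized_side, self.umi_length)


@dataclass
class RunReport:
    config_echo: dict[str, Any]
    filter_reports: dict[str, FilterReport]
    profiles: dict[str, EnrichmentProfile]
    kappas: dict[str, KappaResult]
    aggregate_profile: EnrichmentProfile
    power: Any
    version: str = __version__
    schema_version: int = REPORT_SCHEMA_VERSION
    timings: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": self.schema_version,
            "software_version": self.version,
            "config": self.config_echo,
            "samples": {
                name: json.loads(fr.to_json())
                for name, fr in self.filter_reports.items()
            },
            "kappa": {
                name: dataclasses.asdict(k) for name, k in self.kappas.items()
            },
            "power": {
                "kappa_avg": self.power.kappa_avg,
                "label": self.power.label.value,
                "n_replicates": self.power.n_replicates,
            },
            "aggregate_r": self.aggregate_profile.r.tolist(),
            "positions": self.aggregate_profile.positions,
            "labels": self.aggregate_profile.labels,
        }


def _timed(timings: dict[str, float], stage: str, sample: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, sample, exc) from exc
    dt = time.perf_counter() - t0
    timings[f"{stage}:{sample}"] = round(dt, 4)
    logger.info("stage %s sample %s finished in %.2fs", stage, sample, dt)
    return result


def run(config: RunConfig) -> RunReport:
    """Execute the full analysis and write outputs to ``config.out_dir``."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = config.layout
    timings: dict[str, float] = {}

    pre_sample = next(s for s in config.samples if s.role == "pre")
    post_samples = sorted(
        (s for s in config.samples if s.role == "post"), key=lambda s: s.replicate
    )

    filter_reports: dict[str, FilterReport] = {}
    kept_by_sample: dict[str, list] = {}
    for sample in [pre_sample, *post_samples]:
        name = f"{sample.role}:{sample.replicate}"
        kept, report = _timed(
            timings, "extract", name, extract_fastq,
            sample.fastq, layout, config.max_mismatches,
        )
        filter_reports[name] = report
        kept_by_sample[name] = kept
        (out_dir / f"filter_{sample.role}_{sample.replicate}.json").write_text(
            report.to_json()
        )

    pre_name = f"pre:{pre_sample.replicate}"
    pre_counts = _timed(
        timings, "tally", pre_name, tally,
        kept_by_sample[pre_name], config.site, config.randomized_side,
    )

    profiles: dict[str, EnrichmentProfile] = {}
    kappas: dict[str, KappaResult] = {}
    for sample in post_samples:
        name = f"post:{sample.replicate}"
        counts = _timed(
            timings, "tally", name, tally,
            kept_by_sample[name], config.site, config.randomized_side,
        )
        profile = _timed(
            timings, "enrichment", name, enrichment,
            pre_counts, counts, config.pseudocount, sample.replicate,
        )
        profiles[name] = profile
        stats_ = _timed(timings, "umi_stats", name, umi_stats, kept_by_sample[name])
        kappas[name] = _timed(
            timings, "kappa", name, kappa, stats_, config.kappa_literal_orientation
        )
        write_profile_tsv(profile, out_dir / f"profile_{sample.replicate}.tsv")

    agg = _timed(
        timings, "aggregate", "all", aggregate, list(profiles.values())
    )
    write_profile_tsv(agg, out_dir / "profile_aggregate.tsv")

    power = classify(list(kappas.values()))
    if power.label.value != "well_powered":
        logger.warning(
            "kappa_avg %.3f classified as %s", power.kappa_avg, power.label.value
        )
    with open(out_dir / "kappa.tsv", "w") as fh:
        fh.write("replicate\tslope\tr_squared\tkappa\n")
        for name, k in kappas.items():
            fh.write(f"{name}\t{k.slope:.6g}\t{k.r_squared:.6g}\t{k.kappa:.6g}\n")

    config_echo = {
        "site": config.site.name,
        "site_sequence": config.site.sequence,
        "randomized_side": config.randomized_side.value,
        "umi_length": config.umi_length,
        "max_mismatches": config.max_mismatches,
        "pseudocount": config.pseudocount,
        "motif_threshold": config.motif_threshold,
        "kappa_literal_orientation": config.kappa_literal_orientation,
        "seed": config.seed,
        "samples": [
            {"role": s.role, "replicate": s.replicate, "fastq": str(s.fastq)}
            for s in config.samples
        ],
    }
    report = RunReport(
        config_echo=config_echo,
        filter_reports=filter_reports,
        profiles=profiles,
        kappas=kappas,
        aggregate_profile=agg,
        power=power,
        timings=timings,
    )
    (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return report


FIXTURES = ("cre-neutral", "cre-selective", "background-heavy")


def fixture(name: str, out_dir: str | Path, seed: int = 0) -> dict[str, Any]:
    """Write a tiny seeded simulation plus its expected-output snapshot."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    out_dir = Path(out_dir)
    spec = LibrarySpec(site="loxP", randomized_side=Side.LEFT)
    half_len = len(spec.canonical_half)
    if name == "cre-neutral":
        model = SelectionModel.neutral(half_len, gamma=0.0, p_max=0.3)
        config = SimConfig(n_molecules=5_000, n_reads=10_000, seed=seed)
    elif name == "cre-selective":
        model = SelectionModel.from_weight_map(spec.canonical_half, 0.5, gamma=1.0)
        config = SimConfig(n_molecules=5_000, n_reads=10_000, seed=seed)
    else:  # background-heavy
        model = SelectionModel.from_weight_map(
            spec.canonical_half, 0.5, gamma=1.0, p_max=0.02, background_survival=0.3
        )
        config = SimConfig(n_molecules=5_000, n_reads=10_000, seed=seed)
    simulate_experiment(spec, model, config, out_dir)
    expected = {
        "fixture": name,
        "expected_r": expected_enrichment(model, spec).tolist(),
        "note": "closed form assumes no background survival",
    }
    (out_dir / "expected.json").write_text(json.dumps(expected, indent=2))
    return expected
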