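"""Shared fixtures: small seeded simulations reused across the suite."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

from recseq.simlib import (
    LibrarySpec,
    SelectionModel,
    SimConfig,
    simulate_experiment,
)
from recseq.targets import LOXP, Side


@dataclass
class SimFixture:
    spec: LibrarySpec
    model: SelectionModel
    config: SimConfig
    out_dir: Path

    @property
    def pre_fastq(self) -> Path:
        return self.out_dir / "pre.fastq"

    @property
    def post_fastq(self) -> Path:
        return self.out_dir / "post.fastq"

    @property
    def manifest_tsv(self) -> Path:
        return self.out_dir / "manifest.tsv"


def _simulate(tmp_factory, name, model, config, spec=None):
    spec = spec or LibrarySpec(site=LOXP, randomized_side=Side.LEFT)
    out_dir = tmp_factory.mktemp(name)
    simulate_experiment(spec, model, config, out_dir)
    return SimFixture(spec, model, config, out_dir)


@pytest.fixture(scope="session")
def sim_clean(tmp_path_factory) -> SimFixture:
    """Noise-free selective simulation: w=0.5, gamma=1, no background."""
    spec = LibrarySpec(site=LOXP, randomized_side=Side.LEFT)
    model = SelectionModel.from_weight_map(spec.canonical_half, 0.5, gamma=1.0)
    config = SimConfig(n_molecules=50_000, n_reads=100_000,
                       mean_reads_per_molecule=3.0, seed=11)
    return _simulate(tmp_path_factory, "sim_clean", model, config, spec)


@pytest.fixture(scope="session")
def sim_neutral(tmp_path_factory) -> SimFixture:
    """Neutral selection (gamma=0): every r_i should be ~1."""
    spec = LibrarySpec(site=LOXP, randomized_side=Side.LEFT)
    model = SelectionModel.neutral(len(spec.canonical_half), gamma=0.0, p_max=0.5)
    config = SimConfig(n_molecules=60_000, n_reads=100_000, seed=23)
    return _simulate(tmp_path_factory, "sim_neutral", model, config, spec)
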