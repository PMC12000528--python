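"""Shared fixtures: small simulated datasets and two end-to-end runs.

The heavy end-to-end fixtures (1 Mb diploid genome at 30x and 15x) are
session-scoped; most tests use tiny purpose-built simulations instead.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pytest

from haplosv import pipeline, simdata
from haplosv.alignio import ReferenceGenome


@dataclass
class E2ERun:
    sim: simdata.SimResult
    ref: ReferenceGenome
    loci: list
    vcf_path: str
    bam_path: str
    sample: str


def _run_end_to_end(tmp_dir: str, depth: float, seed: int = 0) -> E2ERun:
    cfg = simdata.SimConfig(seed=seed, depth=depth)
    sim = simdata.simulate(cfg)
    os.makedirs(tmp_dir, exist_ok=True)
    fa = os.path.join(tmp_dir, "ref.fa")
    bam = os.path.join(tmp_dir, "sample1.bam")
    vcf = os.path.join(tmp_dir, "calls.vcf")
    sim.write_reference(fa)
    sim.write_bam("sample1", bam)
    ref = ReferenceGenome(fa)
    rcfg = pipeline.RunConfig(seed=seed)
    disc = pipeline.discover_sample(bam, ref, "sample1", rcfg)
    loci = pipeline.run_joint_call([disc], {"sample1": bam}, ref, vcf, rcfg)
    return E2ERun(sim, ref, loci, vcf, bam, "sample1")


@pytest.fixture(scope="session")
def e2e_30x(tmp_path_factory) -> E2ERun:
    """Full run under the default study conditions: 1 Mb, 30x, 1% error,
    20 planted SVs spanning the three size strata."""
    return _run_end_to_end(str(tmp_path_factory.mktemp("e2e30")), depth=30.0)


@pytest.fixture(scope="session")
def e2e_15x(tmp_path_factory) -> E2ERun:
    """Same genome and truth at half coverage (coverage-titration arm)."""
    return _run_end_to_end(str(tmp_path_factory.mktemp("e2e15")), depth=15.0)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory) -> dict:
    """150 kb single-sample simulation with one SV of each class."""
    cfg = simdata.SimConfig(
        seed=11, contig_len=150_000, depth=30, error_rate=0.01,
        sv_plan=[("DEL", 100), ("INS", 200), ("DUP", 90), ("INV", 900), ("DEL", 2500)],
    )
    sim = simdata.simulate(cfg)
    d = str(tmp_path_factory.mktemp("smallsim"))
    fa, bam = os.path.join(d, "ref.fa"), os.path.join(d, "s1.bam")
    sim.write_reference(fa)
    sim.write_bam("sample1", bam)
    return {"sim": sim, "fasta": fa, "bam": bam, "dir": d}
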