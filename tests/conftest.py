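"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from dualism.config import SimulationConfig
from dualism.simulate import (
    simulate_diploid_genome,
    simulate_genic_genome,
    simulate_long_reads,
)
from dualism import ghmm


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        genome_length=200_000,
        n_contigs=2,
        coverage_per_library=40,
        read_length=3000,
        seed=101,
    )


@pytest.fixture(scope="session")
def diploid(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("diploid")
    return simulate_diploid_genome(small_config, outdir)


@pytest.fixture(scope="session")
def mic_mac_sams(diploid, small_config, tmp_path_factory):
    d = tmp_path_factory.mktemp("reads")
    paths = {}
    for lib in ("MIC", "MAC"):
        paths[lib] = d / f"{lib.lower()}.sam"
        simulate_long_reads(diploid, lib, small_config, paths[lib])
    return paths


@pytest.fixture(scope="session")
def trained_ghmm():
    """Params fitted on 300 simulated genes plus the training corpus."""
    cfg = SimulationConfig(seed=202)
    contigs, genes = simulate_genic_genome(cfg, n_contigs=150, genes_per_contig=2)
    params = ghmm.fit_ghmm(genes, contigs)
    return cfg, params


def make_sam(path, contigs, reads):
    """Write a hand-constructed SAM file.

    ``reads`` is a list of (name, contig, pos, cigar_string, seq, tags)
    where tags is an optional dict of SAM aux tags.
    """
    import pysam

    from dualism.io_utils import sam_header

    header = sam_header(contigs)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        rows = []
        for name, contig, pos, cigar, seq, *rest in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.flag = 0
            a.reference_id = header.get_tid(contig)
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.query_sequence = seq
            if rest and rest[0]:
                for k, v in rest[0].items():
                    a.set_tag(k, v)
            rows.append(a)
        rows.sort(key=lambda a: (a.reference_id, a.reference_start))
        for a in rows:
            out.write(a)
    return path
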