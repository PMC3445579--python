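"""Nonparametric bootstrap over characters for clade support.

Each replicate resamples the matrix's characters with replacement (same
count, carrying each column's ordered flag along), reruns a reduced
heuristic search, and takes the majority-rule consensus of the resulting
shortest trees. A clade's support is the fraction of replicate consensus
trees containing it. Fully deterministic under the configured seed;
replicate streams are spawned from an independent child of the run seed so
bootstrap and primary search never share a random stream.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import replace

import numpy as np

from ..config import PipelineConfig
from ..errors import ValidationError
from .consensus import majority_consensus
from .matrix import CharacterMatrix
from .search import search

__all__ = ["bootstrap_support"]


def bootstrap_support(
    matrix: CharacterMatrix,
    cfg: PipelineConfig | None = None,
    n_replicates: int | None = None,
) -> dict[frozenset, float]:
    """Clade -> support proportion from character-resampling bootstrap.

    Clades are keyed by the leaf-name frozenset on the side of the
    bipartition not containing the outgroup (or the lexicographically
    smallest taxon when no outgroup is set).
    """
    cfg = cfg or PipelineConfig()
    n_rep = n_replicates if n_replicates is not None else cfg.n_bootstrap_replicates
    if n_rep < 1:
        raise ValidationError("need at least one bootstrap replicate")
    reference = matrix.outgroup if matrix.outgroup is not None else min(matrix.taxa)
    nchar = matrix.n_characters
    # child 1 of the run seed: disjoint from the primary search (child 0 space)
    root_ss = np.random.SeedSequence(cfg.rng_seed, spawn_key=(1,))
    streams = root_ss.spawn(n_rep)
    counts: Counter = Counter()
    for rep_stream in streams:
        rng = np.random.default_rng(rep_stream)
        cols = rng.integers(0, nchar, size=nchar)
        resampled = matrix.resample_characters(cols)
        rep_cfg = replace(
            cfg,
            rng_seed=int(rng.integers(2**31)),
            n_random_additions=cfg.bootstrap_n_random_additions,
        )
        result = search(resampled, rep_cfg)
        consensus = majority_consensus(result.mpt_set)
        counts.update(consensus.bipartitions(reference).keys())
    return {clade: c / n_rep for clade, c in counts.items()}
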