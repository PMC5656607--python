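"""Consensus voting over caller outputs and the force-called count matrix.

Somatic callers disagree; a variant is kept in a sample only when at least
``min_callers`` independent callers report it there.  The union of every
kept variant across a patient's samples is then "force-called": alt/ref
read counts are looked up at every (variant, sample) pair so that a
variant private to one biopsy still has an explicit (often 0/N) count in
every other biopsy, rather than a missing cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Set, Tuple

import pandas as pd

from .types import Effect, NONSILENT_EFFECTS, ParameterError

logger = logging.getLogger(__name__)

__all__ = ["ForceCallMatrix", "consensus_vote", "build_force_call_matrix", "is_nonsilent"]


@dataclass
class ForceCallMatrix:
    """Complete (variant x sample) alt/ref count matrix for one patient.

    ``alt`` and ``ref`` are DataFrames indexed by variant key with one
    column per sample; by construction they share shape and have no gaps.
    """

    alt: pd.DataFrame
    ref: pd.DataFrame

    @property
    def variant_keys(self):
        return list(self.alt.index)

    @property
    def sample_ids(self):
        return list(self.alt.columns)

    def counts(self, key, sample_id) -> Tuple[int, int]:
        return int(self.alt.at[key, sample_id]), int(self.ref.at[key, sample_id])


def consensus_vote(
    calls_by_caller: Mapping[str, Iterable], min_callers: int = 2
) -> Set:
    """Variants reported by at least ``min_callers`` of the given callers.

    Variant identity is whatever hashable key the call sets contain
    (conventionally (sample_id, chrom, pos, ref, alt)).
    """
    if min_callers < 1:
        raise ParameterError(f"min_callers must be >= 1, got {min_callers}")
    if not calls_by_caller:
        raise ParameterError("at least one caller set is required")
    votes: Dict[object, int] = {}
    for calls in calls_by_caller.values():
        for v in set(calls):
            votes[v] = votes.get(v, 0) + 1
    kept = {v for v, n in votes.items() if n >= min_callers}
    logger.info(
        "consensus vote: %d/%d variants kept (min_callers=%d)",
        len(kept), len(votes), min_callers,
    )
    return kept


def build_force_call_matrix(
    variant_keys: Iterable,
    sample_ids: Sequence[str],
    counts: Mapping[Tuple[object, str], Tuple[int, int]],
) -> ForceCallMatrix:
    """Assemble the complete count matrix from a (variant, sample) lookup.

    ``counts`` must cover every pair; a missing entry raises an error
    naming it (real data would need a pileup step to fill these in).
    """
    keys = sorted(set(variant_keys))
    missing = [(k, s) for k in keys for s in sample_ids if (k, s) not in counts]
    if missing:
        shown = ", ".join(f"({k}, {s})" for k, s in missing[:5])
        raise KeyError(
            f"counts lookup missing {len(missing)} (variant, sample) pair(s): {shown}"
        )
    alt = pd.DataFrame(
        [[counts[(k, s)][0] for s in sample_ids] for k in keys],
        index=keys, columns=list(sample_ids), dtype=int,
    )
    ref = pd.DataFrame(
        [[counts[(k, s)][1] for s in sample_ids] for k in keys],
        index=keys, columns=list(sample_ids), dtype=int,
    )
    return ForceCallMatrix(alt=alt, ref=ref)


def is_nonsilent(effect: Effect) -> bool:
    """True for protein-altering effect classes."""
    if not isinstance(effect, Effect):
        effect = Effect(effect)
    return effect in NONSILENT_EFFECTS
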