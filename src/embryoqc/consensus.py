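"""Consensus reference construction from replicate genotyping runs.

When replicate runs of the same (unamplified) DNA disagree at a locus, the
consensus genotype is taken; when no consensus can be determined, a no-call
is produced.
"""

from __future__ import annotations

import numpy as np

from .matrix import HET, HOM_A, HOM_B, NO_CALL, GenotypeMatrix


def build_consensus(replicates: list[GenotypeMatrix], min_agree: int = 2) -> GenotypeMatrix:
    """Per-cell modal call across replicates.

    A cell receives the modal non-missing call if its multiplicity is at
    least ``min_agree`` and it is the unique mode; otherwise NO_CALL.  With
    the default ``min_agree=2`` a lone call among no-calls is conservatively
    discarded; pass ``min_agree=1`` for any-replicate accounting.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    if min_agree < 1:
        raise ValueError("min_agree must be >= 1")
    first = replicates[0]
    for r in replicates[1:]:
        if r.sample_ids != first.sample_ids or not r.same_loci(first):
            raise ValueError("replicates must share sample and locus ordering")

    stack = np.stack([r.calls for r in replicates])  # (k, n, L)
    votes = np.stack([(stack == g).sum(axis=0) for g in (HOM_A, HET, HOM_B)])
    top = votes.max(axis=0)
    n_modes = (votes == top).sum(axis=0)
    modal = votes.argmax(axis=0).astype(np.int8)
    consensus = np.where((top >= min_agree) & (n_modes == 1), modal, NO_CALL).astype(np.int8)
    return GenotypeMatrix(list(first.sample_ids), first.loci.copy(), consensus)
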