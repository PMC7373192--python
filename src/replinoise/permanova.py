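"""Permutational MANOVA (one factor) on a distance matrix.

Implements the pseudo-F permutation test of community difference used to
ask whether samples differ from their controls.  The package carries its
own implementation so that the pipeline can demonstrate its central
caution end to end: with technical replicates treated as free exchangeable
units, a noise-dominated sample set can test "significantly different"
from its controls while being entirely irreproducible between replicates.
Block permutation (whole specimens permuted together) is offered for the
honest version of the test.

The statistic follows the standard distance-based decomposition: with n
samples in g groups and squared distances d²,

    SS_total   = (1/n)   Σ_{i<j} d²_ij
    SS_within  = Σ_g (1/n_g) Σ_{i<j in g} d²_ij
    SS_between = SS_total − SS_within
    pseudo-F   = (SS_between/(g−1)) / (SS_within/(n−g))

and p = (1 + #{permuted F ≥ observed F}) / (1 + n_permutations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError

__all__ = ["PermanovaResult", "permanova", "pseudo_f"]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    seed: int | None
    blocked: bool = False


def _validate_dm(dm: np.ndarray) -> np.ndarray:
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise FitError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-10):
        raise FitError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dm), 0.0, atol=1e-10):
        raise FitError("distance matrix must have a zero diagonal")
    return dm


def pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from squared distances *d2* and integer group labels.

    Returns 0.0 when the total sum of squares is 0 (all points coincide).
    """
    n = d2.shape[0]
    groups = np.unique(labels)
    g = groups.size
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for grp in groups:
        idx = np.flatnonzero(labels == grp)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += np.triu(sub, k=1).sum() / idx.size
    if ss_total <= 0.0:
        return 0.0
    ss_between = ss_total - ss_within
    if ss_within <= 0.0:
        return np.inf if ss_between > 0 else 0.0
    return float((ss_between / (g - 1)) / (ss_within / (n - g)))


def permanova(
    dm: np.ndarray,
    groups: list[str] | np.ndarray,
    n_permutations: int = 999,
    seed: int | None = None,
    block: list[str] | np.ndarray | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA.

    Parameters
    ----------
    dm
        Square symmetric distance matrix with zero diagonal.
    groups
        One label per sample; >= 2 groups with >= 2 members each.
    n_permutations
        Monte-Carlo permutations (>= 99).
    block
        Optional block labels (e.g. specimen IDs).  When given, group
        membership must be constant within a block and whole blocks are
        permuted together — technical replicates are then not treated as
        independent exchangeable units.
    """
    dm = _validate_dm(dm)
    labels = np.asarray([str(x) for x in groups])
    if labels.size != dm.shape[0]:
        raise FitError("one group label per sample is required")
    uniq, enc = np.unique(labels, return_inverse=True)
    sizes = {u: int((labels == u).sum()) for u in uniq}
    if len(uniq) < 2:
        raise FitError("PERMANOVA needs at least 2 groups")
    if min(sizes.values()) < 2:
        raise FitError(f"every group needs >= 2 members, got {sizes}")
    if n_permutations < 99:
        raise FitError("use at least 99 permutations")

    d2 = dm**2
    f_obs = pseudo_f(d2, enc)
    rng = np.random.default_rng(seed)

    if block is None:
        perm_source = enc
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(perm_source)
            if pseudo_f(d2, perm) >= f_obs - 1e-12:
                count += 1
    else:
        blocks = np.asarray([str(b) for b in block])
        if blocks.size != labels.size:
            raise FitError("one block label per sample is required")
        uniq_blocks, block_idx = np.unique(blocks, return_inverse=True)
        block_group = np.empty(uniq_blocks.size, dtype=enc.dtype)
        for i in range(uniq_blocks.size):
            members = enc[block_idx == i]
            if np.unique(members).size != 1:
                raise FitError(
                    f"block {uniq_blocks[i]!r} spans multiple groups; blocks must nest in groups"
                )
            block_group[i] = members[0]
        count = 0
        for _ in range(n_permutations):
            permuted_bg = rng.permutation(block_group)
            perm = permuted_bg[block_idx]
            if pseudo_f(d2, perm) >= f_obs - 1e-12:
                count += 1

    p = (1.0 + count) / (1.0 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=int(n_permutations),
        group_sizes=sizes,
        seed=seed,
        blocked=block is not None,
    )
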