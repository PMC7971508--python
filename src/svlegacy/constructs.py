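"""Reference constructions for the d statistic.

Each helper builds an (ancestral context, derived context, L) pair realizing
one mechanism exactly.  Junctions are made breakpoint-unambiguous: a few
bases on each side of every breakpoint are resampled so that the inserted
sequence cannot seamlessly continue the flank (the same ambiguity that makes
un-normalized indel positions ill-defined: if an insert begins with the same
bases as its right flank, the true breakpoint — and hence the exact d — is
not a well-defined quantity).
"""

from __future__ import annotations

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype="S1")
GUARD = 5  # junction positions forced to mismatch


def _seq(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(_BASES, size=n)


def _guard_against(target: np.ndarray, idx: int, other: np.ndarray, odx: int,
                   n: int, rng: np.random.Generator, step: int = 1) -> None:
    """Force target[idx + k*step] != other[odx + k*step] for k < n."""
    for k in range(n):
        i, o = idx + k * step, odx + k * step
        if 0 <= i < len(target) and 0 <= o < len(other):
            while target[i] == other[o]:
                target[i] = rng.choice(_BASES)


def _txt(*arrays: np.ndarray) -> tuple[str, ...]:
    return tuple(a.tobytes().decode() for a in arrays)


def make_ectopic_case(L: int, seed: int | np.random.Generator = 0) -> tuple[str, str, int]:
    """Direct integration of unrelated DNA: expected d = 0."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lf, rf, ins = _seq(L, rng), _seq(L, rng), _seq(L, rng)
    _guard_against(ins, 0, rf, 0, GUARD, rng)
    _guard_against(ins, L - 1, lf, L - 1, GUARD, rng, step=-1)
    lf_s, rf_s, ins_s = _txt(lf, rf, ins)
    return lf_s + rf_s, lf_s + ins_s + rf_s, L


def make_tandem_case(L: int, seed: int | np.random.Generator = 0) -> tuple[str, str, int]:
    """Perfect tandem duplication of the L bases 5' of the site: expected d = L."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lf, rf = _seq(L, rng), _seq(L, rng)
    _guard_against(rf, 0, lf, 0, GUARD, rng)
    lf_s, rf_s = _txt(lf, rf)
    return lf_s + rf_s, lf_s + lf_s + rf_s, L


def make_slippage_case(
    L: int, seed: int | np.random.Generator = 0, a: int | None = None,
    b: int | None = None, anneal: int | None = None,
) -> tuple[str, str, int, int]:
    """Template-switch at a short annealing site: expected d = a + b > L.

    The insert copies the first `a` bases of the right flank, then — annealing
    at an `anneal`-bp motif shared with the left flank — the last `b` bases of
    the left flank, with a + b = L + anneal.  The two major alignments re-use
    the anneal and overlap by `anneal` bases on the derived sequence, so
    d = a + b = L + anneal.  Returns (ancestral, derived, L, expected_d).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if anneal is None:
        # keep d = L + anneal clear of the tandem tolerance band (5% of L)
        anneal = max(10, int(round(0.15 * L)))
    if a is None:
        a = L // 2 + anneal
    if b is None:
        b = L + anneal - a
    if not (anneal <= min(a, b) and a + b == L + anneal):
        raise ValueError("need anneal <= a, b and a + b = L + anneal")
    m = _seq(anneal, rng)
    lf = np.concatenate([_seq(L - b, rng), m, _seq(b - anneal, rng)])  # ... m l
    rf = np.concatenate([_seq(a - anneal, rng), m, _seq(L - a, rng)])  # r m ...
    # breakpoint-unambiguity guards at the copy boundaries
    _guard_against(lf, L - b + anneal, rf, a, GUARD, rng)          # S end vs Rf cont.
    _guard_against(rf, a - anneal - 1, lf, L - b - 1, GUARD, rng, step=-1)
    ins = np.concatenate([rf[:a], lf[L - b + anneal:]])
    assert len(ins) == L
    lf_s, rf_s, ins_s = _txt(lf, rf, ins)
    return lf_s + rf_s, lf_s + ins_s + rf_s, L, a + b


def make_embedded_ectopic(
    genome_length: int, L: int, seed: int | np.random.Generator = 0
) -> tuple[str, str, int]:
    """Ectopic insertion embedded in a larger sequence.

    A random ancestral sequence of `genome_length` bp receives an
    independently generated `L` bp insert at its midpoint; the returned
    contexts carry `L` bp flanks cut from the embedding sequence.  Junction
    guards as in :func:`make_ectopic_case`.  Expected d = 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if genome_length < 4 * L:
        raise ValueError("genome too short for the requested flanks")
    genome = _seq(genome_length, rng)
    mid = genome_length // 2
    ins = _seq(L, rng)
    _guard_against(ins, 0, genome, mid, GUARD, rng)
    _guard_against(ins, L - 1, genome, mid - 1, GUARD, rng, step=-1)
    derived = np.concatenate([genome[:mid], ins, genome[mid:]])
    anc_ctx = genome[mid - L : mid + L]
    der_ctx = derived[mid - L : mid + 2 * L]
    (anc_s, der_s) = _txt(anc_ctx, der_ctx)
    return anc_s, der_s, L


def make_deletion_case(L: int, seed: int | np.random.Generator = 0) -> tuple[str, str, int]:
    """Removal of unrelated sequence: ancestral context 3L, derived 2L."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lf, rf, dele = _seq(L, rng), _seq(L, rng), _seq(L, rng)
    _guard_against(dele, 0, rf, 0, GUARD, rng)
    _guard_against(dele, L - 1, lf, L - 1, GUARD, rng, step=-1)
    lf_s, rf_s, del_s = _txt(lf, rf, dele)
    return lf_s + del_s + rf_s, lf_s + rf_s, L
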