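"""Numba kernels for the adaptive context-model arithmetic coder.

The coder works over the 5-symbol alphabet {A,C,G,T,N} encoded as the
integers 0..4.  A fixed-order context model (default order 8) keeps
one count row per context; symbol probabilities use additive smoothing
with asymmetric prior weights (1/4 for each of A,C,G,T and 1/16 for N,
one unit per observation), so every symbol is always codable and no
escape mechanism is needed.  The weights are stored as integers scaled
by 16: a fresh context row is [4, 4, 4, 4, 1] and each observation
adds 16.  A fresh context therefore costs about 2.09 bits per A/C/G/T
symbol (close to the 2-bit floor of uniform DNA rather than the naive
log2(5)), while a single prior observation of the correct symbol drops
the cost to about 0.72 bits — the strong one-shot adaptation that
conditional compression relies on.  Counts are updated after each
coded symbol, which makes the model adaptive and makes conditional
compression possible: priming the counts with one sequence before
encoding another.

The entropy coder itself is a classic 32-bit integer arithmetic coder
with underflow (pending-bit) handling.  All kernels are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint8

N_SYMBOLS = 5

# prior pseudo-counts and per-observation increment, scaled by 16 so
# the table stays integral: priors 1/4 (A,C,G,T) and 1/16 (N), one
# unit per observation
PRIOR_ACGT = 4
PRIOR_N = 1
INCREMENT = 16

_TOP = np.uint64(0xFFFFFFFF)
_HALF = np.uint64(0x80000000)
_QUARTER = np.uint64(0x40000000)
_THREE_QUARTER = np.uint64(0xC0000000)


@njit(cache=True)
def _put_bit(out, nbits, bit):
    byte_i = nbits >> 3
    if bit:
        out[byte_i] |= uint8(0x80) >> uint8(nbits & 7)
    return nbits + 1


@njit(cache=True)
def _put_bit_plus_pending(out, nbits, bit, pending):
    nbits = _put_bit(out, nbits, bit)
    inv = 1 - bit
    for _ in range(pending):
        nbits = _put_bit(out, nbits, inv)
    return nbits


@njit(cache=True)
def new_counts(order):
    """Fresh count table (prior pseudo-counts only) for the given order."""
    n_ctx = 1
    for _ in range(order):
        n_ctx *= N_SYMBOLS
    counts = np.empty((n_ctx, N_SYMBOLS), dtype=np.uint32)
    counts[:, :4] = PRIOR_ACGT
    counts[:, 4] = PRIOR_N
    return counts


@njit(cache=True)
def update_counts(seq, counts):
    """One adaptive pass over ``seq`` updating ``counts``; no output.

    Used to prime a model on a conditioning sequence.  The rolling
    context starts at 0 (as if preceded by A's) exactly as in encoding.
    """
    n_ctx = counts.shape[0]
    ctx = 0
    for i in range(seq.shape[0]):
        s = seq[i]
        counts[ctx, s] += INCREMENT
        ctx = (ctx * N_SYMBOLS + s) % n_ctx


@njit(cache=True)
def encode_core(seq, counts, out):
    """Arithmetic-encode ``seq`` under the adaptive model in ``counts``.

    ``out`` must be a zeroed uint8 buffer of at least 4*len(seq)+16
    bytes (a safe bound: per-symbol cost is below log2(total/4)+2
    bits, under 32 bits for any payload below ~30 Mb).  Returns the
    number of code bits written.  ``counts`` is mutated (the model
    adapts), so pass a copy if the table must survive.
    """
    n_ctx = counts.shape[0]
    low = np.uint64(0)
    high = _TOP
    pending = 0
    nbits = 0
    ctx = 0
    for i in range(seq.shape[0]):
        s = seq[i]
        # cumulative smoothed frequencies for this context
        cum_lo = np.uint64(0)
        for j in range(s):
            cum_lo += np.uint64(counts[ctx, j])
        cum_hi = cum_lo + np.uint64(counts[ctx, s])
        total = cum_hi
        for j in range(s + 1, N_SYMBOLS):
            total += np.uint64(counts[ctx, j])

        span = high - low + np.uint64(1)
        high = low + (span * cum_hi) // total - np.uint64(1)
        low = low + (span * cum_lo) // total

        while True:
            if high < _HALF:
                nbits = _put_bit_plus_pending(out, nbits, 0, pending)
                pending = 0
            elif low >= _HALF:
                nbits = _put_bit_plus_pending(out, nbits, 1, pending)
                pending = 0
                low -= _HALF
                high -= _HALF
            elif low >= _QUARTER and high < _THREE_QUARTER:
                pending += 1
                low -= _QUARTER
                high -= _QUARTER
            else:
                break
            low = low + low
            high = high + high + np.uint64(1)

        counts[ctx, s] += INCREMENT
        ctx = (ctx * N_SYMBOLS + s) % n_ctx

    # flush: one disambiguating bit plus pending underflow bits
    pending += 1
    if low < _QUARTER:
        nbits = _put_bit_plus_pending(out, nbits, 0, pending)
    else:
        nbits = _put_bit_plus_pending(out, nbits, 1, pending)
    return nbits


@njit(cache=True)
def decode_core(code, n_symbols, counts, out_seq):
    """Decode ``n_symbols`` symbols from the bit buffer ``code``.

    Mirrors :func:`encode_core` exactly (same model updates).  Returns
    the number of code bits consumed, or -1 if the buffer ran out early
    (truncated/corrupt stream).
    """
    n_ctx = counts.shape[0]
    total_bits = code.shape[0] * 8
    low = np.uint64(0)
    high = _TOP
    value = np.uint64(0)
    bit_i = 0
    for _ in range(32):
        value = value + value
        if bit_i < total_bits and (code[bit_i >> 3] >> (7 - (bit_i & 7))) & 1:
            value += np.uint64(1)
        bit_i += 1
    ctx = 0
    for i in range(n_symbols):
        total = np.uint64(0)
        for j in range(N_SYMBOLS):
            total += np.uint64(counts[ctx, j])
        span = high - low + np.uint64(1)
        # scaled target value within [0, total)
        target = ((value - low + np.uint64(1)) * total - np.uint64(1)) // span

        cum_lo = np.uint64(0)
        s = 0
        for j in range(N_SYMBOLS):
            f = np.uint64(counts[ctx, j])
            if cum_lo + f > target:
                s = j
                break
            cum_lo += f
        cum_hi = cum_lo + np.uint64(counts[ctx, s])

        high = low + (span * cum_hi) // total - np.uint64(1)
        low = low + (span * cum_lo) // total

        while True:
            if high < _HALF:
                pass
            elif low >= _HALF:
                low -= _HALF
                high -= _HALF
                value -= _HALF
            elif low >= _QUARTER and high < _THREE_QUARTER:
                low -= _QUARTER
                high -= _QUARTER
                value -= _QUARTER
            else:
                break
            low = low + low
            high = high + high + np.uint64(1)
            value = value + value
            if bit_i < total_bits:
                if (code[bit_i >> 3] >> (7 - (bit_i & 7))) & 1:
                    value += np.uint64(1)
            elif bit_i >= total_bits + 64:
                return -1
            bit_i += 1

        out_seq[i] = s
        counts[ctx, s] += INCREMENT
        ctx = (ctx * N_SYMBOLS + s) % n_ctx

    return bit_i
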