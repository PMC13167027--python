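"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: depth is recounted
position by position in pure Python, Fisher p-values are enumerated in exact
rational arithmetic, and BH is the textbook step-up loop.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np

from symprof.io import AlignmentRecord


def brute_force_depth(records, reference_length: int) -> list[int]:
    """Per-base depth by walking every CIGAR op position by position."""
    depth = [0] * reference_length
    for rec in records:
        pos = rec.pos0
        for n, op in rec.cigar:
            if op in "M=X":
                for i in range(pos, pos + n):
                    depth[i] += 1
                pos += n
            elif op in "DN":
                pos += n
    return depth


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exact rational enumeration over fixed margins."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return Fraction(1)

    def pmf(i: int) -> Fraction:
        return Fraction(
            factorial(r1) * factorial(r2) * factorial(k) * factorial(n - k),
            factorial(n) * factorial(i) * factorial(r1 - i)
            * factorial(k - i) * factorial(r2 - k + i),
        )

    lo, hi = max(0, k - r2), min(k, r1)
    probs = {i: pmf(i) for i in range(lo, hi + 1)}
    observed = probs[a]
    return sum((p for p in probs.values() if p <= observed), Fraction(0))


def bh_oracle(p_values) -> np.ndarray:
    """Textbook BH step-up: q_(i) = min_{j>=i} min(1, p_(j) * m / j)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def random_records(rng: np.random.Generator, reference_length: int, n_reads: int):
    """Random small alignments with CIGARs drawn over {M, D, I, S}."""
    records = []
    for i in range(n_reads):
        pos = int(rng.integers(0, max(1, reference_length - 60)))
        ops = []
        span = 0
        ops.append((int(rng.integers(5, 30)), "M"))
        span += ops[0][0]
        for _ in range(int(rng.integers(0, 3))):
            op = str(rng.choice(["M", "D", "I", "S"]))
            length = int(rng.integers(1, 15))
            if op in "MD":
                if pos + span + length > reference_length:
                    break
                span += length
            ops.append((length, op))
        if pos + span > reference_length:
            pos = reference_length - span
        records.append(
            AlignmentRecord(
                read_id=f"r{i}", ref_id="ref", pos0=pos, cigar=tuple(ops), flags=0, mapq=60
            )
        )
    return records
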