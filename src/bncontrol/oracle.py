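"""Independent brute-force solver: enumerate every control sequence.

Correctness is immediate from the definition — every one of the
``2^(m·τ)`` external-value sequences is simulated and checked — so this is
the ground truth the SCC solver and the backward DP are validated against.
The enumeration is bit-parallel: sequence index ``k`` assigns external ``j``
at time ``t`` the bit ``(k >> (t·m + j)) & 1``, and each node's state over
*all* sequences at once is a ``2^(m·τ)``-bit integer, so one simulation
sweep of the network decides every sequence simultaneously.
"""

from __future__ import annotations

from typing import Iterator

from .expr import python_source
from .network import ControlProblem, ControlSequence

__all__ = [
    "BruteForceCapError",
    "brute_force_solve",
    "brute_force_all",
    "decode_sequence",
]


class BruteForceCapError(RuntimeError):
    """2^(m·τ) exceeds the configured enumeration cap."""


def _position_mask(p: int, total_bits: int) -> int:
    """Integer whose bit k equals ``(k >> p) & 1``, for k in [0, 2^total_bits)."""
    block = 1 << p
    pattern = ((1 << block) - 1) << block  # 2*block bits: low half 0, high half 1
    reps = (1 << total_bits) // (2 * block)
    repunit = ((1 << (reps * 2 * block)) - 1) // ((1 << (2 * block)) - 1)
    return pattern * repunit


def decode_sequence(problem: ControlProblem, index: int) -> ControlSequence:
    """Control sequence number ``index`` in the oracle's enumeration order."""
    m = problem.network.m
    return ControlSequence(
        assignments=tuple(
            {u: (index >> (t * m + j)) & 1 for j, u in enumerate(problem.network.external)}
            for t in range(problem.horizon)
        )
    )


def _solution_mask(problem: ControlProblem, max_sequences: int) -> tuple[int, int]:
    """(mask of valid sequence indices, number of index bits)."""
    net = problem.network
    tau = problem.horizon
    seq_bits = net.m * tau
    if (1 << seq_bits) > max_sequences:
        raise BruteForceCapError(
            f"2^{seq_bits} control sequences exceed the cap of {max_sequences}"
        )
    full = (1 << (1 << seq_bits)) - 1

    state = {v: (full if problem.initial.values[v] else 0) for v in net.internal}
    refs = {v: f"state[{v!r}]" for v in net.internal}
    refs.update({u: f"ext[{u!r}]" for u in net.external})
    exprs = {
        v: compile(python_source(net.functions[v], refs), f"<f_{v}>", "eval")
        for v in net.internal
    }
    for t in range(tau):
        ext = {
            u: _position_mask(t * net.m + j, seq_bits)
            for j, u in enumerate(net.external)
        }
        env = {"state": state, "ext": ext, "FULL": full}
        state = {v: eval(exprs[v], env) for v in net.internal}  # noqa: S307

    match = full
    for v, want in problem.desired.values.items():
        if want is None:
            continue
        match &= state[v] if want else (full ^ state[v])
    return match, seq_bits


def brute_force_solve(
    problem: ControlProblem, *, max_sequences: int = 1 << 24
) -> tuple[int, ControlSequence | None, int]:
    """Exhaustive decision: (decision, first witness or None, solution count)."""
    match, _ = _solution_mask(problem, max_sequences)
    count = match.bit_count()
    if count == 0:
        return 0, None, 0
    witness_index = (match & -match).bit_length() - 1
    return 1, decode_sequence(problem, witness_index), count


def brute_force_all(
    problem: ControlProblem, *, max_sequences: int = 1 << 24
) -> Iterator[int]:
    """Indices of every valid control sequence, ascending."""
    match, _ = _solution_mask(problem, max_sequences)
    while match:
        low = match & -match
        yield low.bit_length() - 1
        match ^= low
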