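"""Plain-text file formats.

Network files use a BoolNet-style "targets, factors" dialect::

    # comment
    targets, factors
    externals: U1, U2, U3
    SLP, SLP
    wg, ((CIA & SLP & !CIR) | (wg & (CIA | SLP) & !CIR)) & U2

One line per internal node (``target, update-expression``); the
``externals:`` directive declares control nodes; ``#`` starts a comment; the
optional ``targets, factors`` header keeps files loadable by BoolNet-family
tools.  Operators are ``& | !`` on output, with ``∧ ∨ ¬`` accepted on input.

Problem files are YAML with keys ``tau``, ``initial`` (node -> 0/1),
``desired`` (node -> 0/1 or ``"-"`` for don't-care) and optionally
``externals`` (cross-checked against the network).  Control-sequence files
are TSV: a header row of external names, then one row of bits per time
step; a trailing row for time τ is accepted and ignored with a warning,
since an assignment at the horizon cannot influence the state there.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import yaml

from .expr import parse_expression, render
from .network import (
    BooleanNetwork,
    ControlProblem,
    ControlSequence,
    NetworkState,
    NetworkValidationError,
)

__all__ = [
    "NetworkFormatError",
    "read_network",
    "write_network",
    "read_problem",
    "write_problem",
    "read_controls",
    "write_controls",
]


class NetworkFormatError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


def read_network(path: str | Path) -> BooleanNetwork:
    """Parse a network file; raises :class:`NetworkFormatError` with line numbers."""
    internal: list[str] = []
    external: list[str] = []
    functions = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().replace(" ", "") == "targets,factors":
            continue
        if line.lower().startswith("externals:"):
            names = [x.strip() for x in line.split(":", 1)[1].split(",") if x.strip()]
            external.extend(names)
            continue
        if "," not in line:
            raise NetworkFormatError("expected 'target, expression'", lineno)
        target, expr_text = line.split(",", 1)
        target = target.strip()
        if target in functions:
            raise NetworkFormatError(f"duplicate target {target!r}", lineno)
        try:
            functions[target] = parse_expression(expr_text.strip())
        except ValueError as exc:
            raise NetworkFormatError(f"bad expression for {target!r}: {exc}", lineno)
        internal.append(target)
    if not internal:
        raise NetworkFormatError("no internal node definitions found")
    try:
        return BooleanNetwork(
            internal=tuple(internal), external=tuple(external), functions=functions
        )
    except NetworkValidationError as exc:
        raise NetworkFormatError(str(exc))


def write_network(network: BooleanNetwork, path: str | Path) -> None:
    lines = ["targets, factors"]
    if network.external:
        lines.append("externals: " + ", ".join(network.external))
    lines += [f"{v}, {render(network.functions[v])}" for v in network.internal]
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_bit(value, node: str, allow_dontcare: bool) -> int | None:
    if allow_dontcare and value in ("-", None):
        return None
    if value in (0, 1):
        return int(value)
    if isinstance(value, str) and value.strip() in ("0", "1"):
        return int(value.strip())
    raise NetworkFormatError(f"value for {node!r} must be 0 or 1, got {value!r}")


def read_problem(path: str | Path, network: BooleanNetwork) -> ControlProblem:
    """Load a YAML control problem and validate it against the network."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise NetworkFormatError("problem file must be a YAML mapping")
    for key in ("tau", "initial", "desired"):
        if key not in doc:
            raise NetworkFormatError(f"problem file misses key {key!r}")
    if "externals" in doc and tuple(doc["externals"]) != network.external:
        raise NetworkFormatError(
            f"problem externals {list(doc['externals'])} do not match the "
            f"network's {list(network.external)}"
        )
    tau = int(doc["tau"])
    initial = {v: _parse_bit(doc["initial"].get(v), v, False) for v in network.internal}
    desired = {v: _parse_bit(doc["desired"].get(v), v, True) for v in network.internal}
    return ControlProblem(
        network=network,
        initial=NetworkState(0, initial),
        desired=NetworkState(tau, desired),
        horizon=tau,
    )


def write_problem(problem: ControlProblem, path: str | Path) -> None:
    net = problem.network
    doc = {
        "externals": list(net.external),
        "tau": problem.horizon,
        "initial": {v: int(problem.initial.values[v]) for v in net.internal},
        "desired": {
            v: ("-" if problem.desired.values[v] is None else int(problem.desired.values[v]))
            for v in net.internal
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_controls(path: str | Path, network: BooleanNetwork, horizon: int) -> ControlSequence:
    """TSV control table: header of external names, one bit row per time step."""
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines:
        raise NetworkFormatError("empty control file")
    header = tuple(x.strip() for x in lines[0].split("\t"))
    if set(header) != set(network.external):
        raise NetworkFormatError(
            f"control columns {list(header)} do not match externals {list(network.external)}"
        )
    rows = []
    for lineno, raw in enumerate(lines[1:], start=2):
        bits = [x.strip() for x in raw.split("\t")]
        if len(bits) != len(header):
            raise NetworkFormatError("wrong number of columns", lineno)
        rows.append({u: _parse_bit(b, u, False) for u, b in zip(header, bits)})
    if len(rows) == horizon + 1:
        warnings.warn(
            "control file has an assignment for time τ, which cannot influence "
            "the state at τ; ignoring the trailing row",
            stacklevel=2,
        )
        rows = rows[:horizon]
    if len(rows) != horizon:
        raise NetworkFormatError(
            f"expected {horizon} control rows, found {len(rows)}"
        )
    return ControlSequence(assignments=tuple(rows))


def write_controls(controls: ControlSequence, network: BooleanNetwork, path: str | Path) -> None:
    lines = ["\t".join(network.external)]
    for a in controls.assignments:
        lines.append("\t".join(str(int(a[u])) for u in network.external))
    Path(path).write_text("\n".join(lines) + "\n")
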