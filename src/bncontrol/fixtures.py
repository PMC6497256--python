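"""Published model fixtures: Drosophila segment-polarity, the four-node
didactic network, and the T-cell receptor state table.

The Drosophila melanogaster segment-polarity subnetwork has 15 internal
genes (mRNAs in lower case, proteins in upper case — ``wg`` and ``WG`` are
distinct nodes) plus three added control inputs U1–U3 wired into ``ptc``,
``wg`` and ``hh`` respectively.  The didactic four-node network has one
control ``u`` driving a two-node feedback pair: ``u = 1`` forces
``(v1, v2) = (1, 0)`` at the next step, ``u = 0`` makes the pair exchange
values; ``v3`` copies ``v1`` and ``v4`` = ``v2 ∧ v3``.  Only the printed
state table of the T-cell receptor model is packaged — its wiring diagram
is not — so it ships as data, not as a runnable network.
"""

from __future__ import annotations

import pandas as pd

from .expr import parse_expression
from .network import BooleanNetwork, ControlProblem, NetworkState

__all__ = [
    "drosophila_fixture",
    "fig6_fixture",
    "fig6_problem",
    "tcell_states_fixture",
    "data_path",
]


def data_path(name: str):
    """Path of a packaged fixture file (also shipped in the network/problem formats)."""
    from importlib.resources import files

    return files("bncontrol").joinpath("data", name)

_DROSOPHILA_RULES = {
    "SLP": "SLP",
    "wg": "((CIA & SLP & !CIR) | (wg & (CIA | SLP) & !CIR)) & U2",
    "WG": "wg",
    "en": "!SLP",
    "EN": "en",
    "hh": "EN & !CIR & U3",
    "HH": "hh",
    "ptc": "CIA & !EN & !CIR & U1",
    "PTC": "ptc & PTC",
    "PH": "PTC",
    "SMO": "!PTC",
    "ci": "!EN",
    "CI": "ci",
    "CIA": "CI & SMO",
    "CIR": "CI & !SMO",
}

# node -> (initial at t=0, desired at t=6)
_DROSOPHILA_STATES = {
    "en": (0, 1),
    "EN": (0, 1),
    "SLP": (0, 0),
    "wg": (1, 0),
    "WG": (1, 0),
    "ptc": (0, 0),
    "PTC": (0, 0),
    "CIA": (0, 0),
    "CIR": (1, 0),
    "ci": (0, 0),
    "CI": (1, 0),
    "SMO": (0, 1),
    "PH": (0, 0),
    "hh": (1, 0),
    "HH": (0, 1),
}

DROSOPHILA_HORIZON = 6


def drosophila_fixture() -> tuple[BooleanNetwork, ControlProblem]:
    """The 15-gene Drosophila network with controls U1–U3 and its τ=6 problem."""
    network = BooleanNetwork(
        internal=tuple(_DROSOPHILA_RULES),
        external=("U1", "U2", "U3"),
        functions={v: parse_expression(f) for v, f in _DROSOPHILA_RULES.items()},
    )
    initial = NetworkState(0, {v: s[0] for v, s in _DROSOPHILA_STATES.items()})
    desired = NetworkState(
        DROSOPHILA_HORIZON, {v: s[1] for v, s in _DROSOPHILA_STATES.items()}
    )
    problem = ControlProblem(
        network=network, initial=initial, desired=desired, horizon=DROSOPHILA_HORIZON
    )
    return network, problem


_FIG6_RULES = {
    "v1": "u | (!u & v2)",
    "v2": "!u & v1",
    "v3": "v1",
    "v4": "v2 & v3",
}


def fig6_fixture() -> tuple[BooleanNetwork, NetworkState]:
    """The didactic four-node network and its all-zero initial state.

    The published initial values cover v1..v3 (all 0); v4's initial value is
    not printed and is set to 0 here — no packaged expectation depends on it.
    """
    network = BooleanNetwork(
        internal=("v1", "v2", "v3", "v4"),
        external=("u",),
        functions={v: parse_expression(f) for v, f in _FIG6_RULES.items()},
    )
    return network, NetworkState(0, {"v1": 0, "v2": 0, "v3": 0, "v4": 0})


def fig6_problem(tau: int = 3) -> ControlProblem:
    """Control problem whose desired state is the one reached under u = (1,0,0,...).

    With that target the solver's search fixes the control sequence
    ``1, 0, 0, 0`` — row #2 of the component state space — reproducing the
    worked ϒ tables.
    """
    from .network import ControlSequence, simulate

    network, initial = fig6_fixture()
    controls = ControlSequence(
        assignments=tuple({"u": 1 if t == 0 else 0} for t in range(tau))
    )
    final = simulate(network, initial, controls)[-1]
    return ControlProblem(
        network=network,
        initial=initial,
        desired=NetworkState(tau, dict(final.values)),
        horizon=tau,
    )


_TCELL_ROWS = [
    ("CD45", 1, 1), ("CD4", 0, 0), ("TCRbind", 0, 1), ("TCRlig", 1, 1),
    ("PAGCsk", 0, 1), ("cCbl", 0, 0), ("NFAT", 0, 0), ("Fyn", 0, 1),
    ("Lck", 1, 0), ("Calcin", 0, 0), ("TCRphos", 0, 1), ("Rlk", 0, 0),
    ("ZAP-70", 0, 0), ("Caplus", 0, 0), ("LATphop", 0, 0), ("Gads", 0, 0),
    ("IP3", 0, 0), ("SLP76", 0, 0), ("Itk", 0, 0), ("PLCgact", 1, 0),
    ("Grb2Sas", 0, 0), ("PLCgbind", 0, 0), ("DAG", 0, 0), ("Ras", 0, 0),
    ("RasGRP1", 0, 0), ("PKCth", 1, 1), ("CRE", 0, 0), ("Raf", 0, 0),
    ("SEK", 0, 1), ("IKKbeta", 0, 1), ("CREB", 1, 0), ("MEK", 0, 1),
    ("AP1", 0, 0), ("JNK", 0, 1), ("IKB", 1, 0), ("Rsk", 0, 0),
    ("ERK", 0, 0), ("Fos", 1, 0), ("JUN", 0, 1), ("NFkB", 0, 1),
]

TCELL_HORIZON = 5


def tcell_states_fixture() -> pd.DataFrame:
    """Initial/desired states of the 40-node T-cell receptor model (τ = 5).

    Update functions are not included (the published wiring exists only as a
    figure); the table supports dimensional checks and external analyses.
    """
    df = pd.DataFrame(_TCELL_ROWS, columns=["node", "initial", "desired"])
    df.attrs["horizon"] = TCELL_HORIZON
    return df
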