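"""Nearest-neighbor duplex melting temperatures.

Primer pairing uses similarity in melting temperature as a selection rule,
so a deterministic Tm estimate is needed.  The model is the unified
nearest-neighbor parameter set with a monovalent-salt correction:

    Tm(K) = 1000 * dH / (dS + R * ln(C_T / x)),   then
    Tm(C) = Tm(K) - 273.15 + 16.6 * log10([Na+])

with dH the summed stack + initiation enthalpies (kcal/mol), dS the summed
entropies (cal/mol/K), R the gas constant, C_T the total oligo
concentration and x = 4 for non-self-complementary oligos (1 for
self-complementary ones).  Parameters are shipped as a JSON table so users
can swap in an alternative set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

from . import iupac

R_GAS = 1.98720425864083  # cal / (mol K)

_DEFAULT_TABLE = "nn_santalucia98.json"


def _load_table(name: str) -> dict:
    with resources.files("taxoprimer.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class ThermoParams:
    """Nearest-neighbor tables plus solution conditions.

    ``nn_enthalpy`` / ``nn_entropy`` hold the ten unique dinucleotide
    stacks (5'->3' top strand); ``init_*`` the per-terminal-pair duplex
    initiation terms.  Defaults: 50 mM monovalent salt, 250 nM total
    oligo, the unified 1998 parameter set.
    """

    nn_enthalpy: dict = field(default_factory=dict)
    nn_entropy: dict = field(default_factory=dict)
    init_enthalpy: dict = field(default_factory=dict)
    init_entropy: dict = field(default_factory=dict)
    monovalent_salt_molar: float = 0.05
    oligo_concentration_molar: float = 2.5e-7

    @classmethod
    def default(cls, **overrides) -> "ThermoParams":
        raw = _load_table(_DEFAULT_TABLE)
        return cls(
            nn_enthalpy={k: v["dh"] for k, v in raw["stacks"].items()},
            nn_entropy={k: v["ds"] for k, v in raw["stacks"].items()},
            init_enthalpy={k: v["dh"] for k, v in raw["initiation"].items()},
            init_entropy={k: v["ds"] for k, v in raw["initiation"].items()},
            **overrides,
        )

    def __post_init__(self):
        if self.nn_enthalpy:
            missing = _TEN_STACKS - set(self.nn_enthalpy)
            if missing:
                raise ValueError(f"nearest-neighbor table missing stacks: {sorted(missing)}")
            for table in (self.nn_enthalpy, self.nn_entropy):
                for v in table.values():
                    if not math.isfinite(v):
                        raise ValueError("non-finite nearest-neighbor parameter")


_TEN_STACKS = frozenset(
    ["AA", "AT", "TA", "CA", "GT", "CT", "GA", "CG", "GC", "GG"]
)


def _stack_key(dinuc: str, table: dict) -> str:
    if dinuc in table:
        return dinuc
    return iupac.reverse_complement(dinuc)


def _terminal_key(base: str) -> str:
    return "GC" if base in "GC" else "AT"


def melting_temperature(sequence: str, params: ThermoParams | None = None) -> float:
    """Nearest-neighbor Tm in degrees Celsius.

    Requires a concrete (unambiguous) sequence of at least 8 nt; group
    primers in this package are concrete by construction, so ambiguity
    codes are an error rather than an averaging problem.
    """
    if params is None:
        params = ThermoParams.default()
    seq = sequence.upper()
    iupac.validate(seq)
    if not iupac.is_concrete(seq):
        bad = next(i for i, c in enumerate(seq) if c not in iupac.CONCRETE)
        raise ValueError(f"ambiguity code {seq[bad]!r} at position {bad}: Tm needs a concrete sequence")
    if len(seq) < 8:
        raise ValueError(f"sequence of length {len(seq)} too short for a meaningful NN Tm (need >= 8)")

    dh = params.init_enthalpy[_terminal_key(seq[0])] + params.init_enthalpy[_terminal_key(seq[-1])]
    ds = params.init_entropy[_terminal_key(seq[0])] + params.init_entropy[_terminal_key(seq[-1])]
    for i in range(len(seq) - 1):
        key = _stack_key(seq[i : i + 2], params.nn_enthalpy)
        dh += params.nn_enthalpy[key]
        ds += params.nn_entropy[key]

    x = 1.0 if seq == iupac.reverse_complement(seq) else 4.0
    tm_kelvin = 1000.0 * dh / (ds + R_GAS * math.log(params.oligo_concentration_molar / x))
    return tm_kelvin - 273.15 + 16.6 * math.log10(params.monovalent_salt_molar)
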