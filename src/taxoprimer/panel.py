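"""The packaged published assay panel and its loader.

Fifteen diagnostic trnT-F assays — nine species-specific, one genus
(Plantago), two family-level (Apiaceae, Poaceae run singleplex), four
multiplex groups (FLPS, LF, TAT, TZ) — with primer sequences, expected
product sizes and the wet-lab reaction metadata (primer concentration,
annealing temperature, MgCl2).  The loader verifies a checksum and the
structural invariants (15 assays, 27 unique oligos, 4 multiplex groups +
3 singleplex assays) before handing the panel out.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .primerdesign import AssayDefinition, Oligo
from .thermo import ThermoParams, melting_temperature

_PANEL_RESOURCE = "published_panel.tsv"
_PANEL_SHA256 = "6774c35efccf9a2e044713e5b62d95a1de4a203e36dd07645b4500b2b966fc0c"


class FixtureIntegrityError(RuntimeError):
    pass


@dataclass(frozen=True)
class AssayFixture:
    """The published panel: assays plus the raw table."""

    assays: tuple
    table: pd.DataFrame

    @property
    def multiplex_groups(self) -> tuple:
        groups = []
        for g in self.table["multiplex"]:
            if g != "singleplex" and g not in groups:
                groups.append(g)
        return tuple(groups)

    @property
    def singleplex_assays(self) -> tuple:
        return tuple(
            a for a, g in zip(self.assays, self.table["multiplex"]) if g == "singleplex"
        )

    def group(self, name: str) -> tuple:
        return tuple(
            a for a, g in zip(self.assays, self.table["multiplex"]) if g == name
        )

    @property
    def unique_oligos(self) -> tuple:
        seen = {}
        for a in self.assays:
            for p in (a.forward, a.reverse):
                seen.setdefault(p.sequence, p)
        return tuple(seen.values())


def parse_sizes(text: str) -> tuple:
    """``"380"`` -> (380,); ``"198/199"`` -> (198, 199); ``"187-293"`` -> (187, 293)."""
    text = str(text).strip()
    if "/" in text:
        return tuple(int(x) for x in text.split("/"))
    if "-" in text:
        lo, hi = text.split("-")
        return (int(lo), int(hi))
    return (int(text),)


def load_packaged_panel(thermo: ThermoParams | None = None) -> AssayFixture:
    """Load and validate the packaged panel.

    Oligo Tm values are computed on load with the package's
    nearest-neighbor model (the table itself stores only wet-lab
    annealing temperatures, which are metadata, not Tm estimates).
    """
    res = resources.files("taxoprimer.data").joinpath(_PANEL_RESOURCE)
    raw = res.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _PANEL_SHA256:
        raise FixtureIntegrityError(
            f"packaged panel checksum mismatch: {digest} != {_PANEL_SHA256}"
        )
    table = pd.read_csv(res.open(), sep="\t", dtype=str)

    if thermo is None:
        thermo = ThermoParams.default()
    oligo_cache: dict[str, Oligo] = {}

    def oligo(name: str, seq: str) -> Oligo:
        seq = seq.upper()
        if seq not in oligo_cache:
            oligo_cache[seq] = Oligo(name, seq, melting_temperature(seq, thermo))
        return oligo_cache[seq]

    assays = []
    for row in table.itertuples(index=False):
        assays.append(
            AssayDefinition(
                name=row.assay_name,
                target=row.target,
                level=row.level,
                forward=oligo(row.forward_name, row.forward_seq),
                reverse=oligo(row.reverse_name, row.reverse_seq),
                expected_sizes=parse_sizes(row.expected_sizes),
                metadata={
                    "concentration_um": float(row.conc_um),
                    "annealing_c": float(row.annealing_c),
                    "mgcl2_mm": float(row.mgcl2_mm),
                    "multiplex": row.multiplex,
                },
            )
        )
    fixture = AssayFixture(tuple(assays), table)
    _validate(fixture)
    return fixture


def _validate(fixture: AssayFixture) -> None:
    if len(fixture.assays) != 15:
        raise FixtureIntegrityError(f"expected 15 assays, found {len(fixture.assays)}")
    if len(fixture.unique_oligos) != 27:
        raise FixtureIntegrityError(
            f"expected 27 unique oligos, found {len(fixture.unique_oligos)}"
        )
    if len(fixture.multiplex_groups) != 4:
        raise FixtureIntegrityError(
            f"expected 4 multiplex groups, found {fixture.multiplex_groups}"
        )
    if len(fixture.singleplex_assays) != 3:
        raise FixtureIntegrityError(
            f"expected 3 singleplex assays, found {len(fixture.singleplex_assays)}"
        )
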