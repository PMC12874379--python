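"""Per-element parameter tables.

The nonbonded table (well depth epsilon, radius R, default charge) ships as an
editable whitespace-delimited text file; covalent radii and masses used for
bond perception and dynamics are small built-in dictionaries.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class ElementParams:
    """Nonbonded parameters of one element: eps [eV], R [A], charge [e]."""

    epsilon: float
    radius: float
    charge: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.radius <= 0:
            raise ValueError(f"R must be > 0, got {self.radius}")


# Covalent radii [A] (Cordero et al. compilation), for bond perception.
COVALENT_RADII = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "Na": 1.66,
    "Cl": 1.02,
}

# Atomic masses [amu].
MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Cl": 35.45,
}


def parse_element_table(text: str) -> dict[str, ElementParams]:
    """Parse a whitespace-delimited ``element eps_eV R_A charge_e`` table.

    Lines starting with ``#`` and blank lines are ignored; the charge column
    is optional and defaults to zero.
    """
    table: dict[str, ElementParams] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise ValueError(
                f"element table line {lineno}: expected "
                f"'element eps R [charge]', got {raw!r}"
            )
        elem = parts[0]
        try:
            eps, radius = float(parts[1]), float(parts[2])
            charge = float(parts[3]) if len(parts) == 4 else 0.0
        except ValueError as exc:
            raise ValueError(f"element table line {lineno}: {exc}") from exc
        table[elem] = ElementParams(eps, radius, charge)
    return table


def load_element_table(path: str | Path | None = None) -> dict[str, ElementParams]:
    """Load the element parameter table (packaged default if ``path`` is None)."""
    if path is None:
        text = (
            importlib.resources.files("gridff.data")
            .joinpath("elements.dat")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    return parse_element_table(text)


_DEFAULT_TABLE: dict[str, ElementParams] | None = None


def default_element_table() -> dict[str, ElementParams]:
    """Cached packaged element table."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_element_table()
    return _DEFAULT_TABLE
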