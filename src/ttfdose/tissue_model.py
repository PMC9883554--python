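"""Electrical tissue properties and complex admittivity.

Each tissue class carries a conductivity ``sigma`` (S/m) and a relative
permittivity ``eps_r``.  At an angular frequency ``omega`` the material is
described by the complex admittivity

    kappa = sigma + i * omega * eps0 * eps_r   [S/m]

which combines conduction and displacement currents in the quasi-static
regime.  The default property table ships as a packaged CSV so users can
override individual tissues without touching code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, Mapping, Union

import numpy as np
import pandas as pd

#: Vacuum permittivity, F/m (CODATA 2018).
EPS0 = 8.8541878128e-12

#: Canonical tissue-class names, in table order.
TISSUE_LABELS = (
    "scalp",
    "skull",
    "gray_matter",
    "white_matter",
    "csf",
    "tumor_shell",
    "tumor_core",
    "hydrogel",
    "electrode",
    "air",
)


class UnknownTissueError(KeyError):
    """Raised when a tissue label is not present in the property table."""

    def __init__(self, label: str):
        super().__init__(label)
        self.label = label

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"unknown tissue label: {self.label!r}"


@dataclass(frozen=True)
class TissueProperties:
    """Electrical properties of one tissue class.

    Parameters
    ----------
    label:
        Tissue-class identifier (one of :data:`TISSUE_LABELS` for the
        default table; user tables may add labels).
    sigma:
        Electrical conductivity, S/m.  Must be non-negative.
    eps_r:
        Relative permittivity, dimensionless.  Must be >= 1.
    """

    label: str
    sigma: float
    eps_r: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError(f"{self.label}: sigma must be >= 0, got {self.sigma}")
        if self.eps_r < 1:
            raise ValueError(f"{self.label}: eps_r must be >= 1, got {self.eps_r}")

    def admittivity(self, freq: "FrequencySpec") -> complex:
        """Complex admittivity sigma + i*omega*eps0*eps_r at ``freq``."""
        return complex(self.sigma, freq.omega * freq.eps0 * self.eps_r)


@dataclass(frozen=True)
class FrequencySpec:
    """Working frequency of the applied field (default 200 kHz)."""

    frequency: float = 200_000.0
    eps0: float = EPS0

    def __post_init__(self):
        if self.frequency < 0:
            raise ValueError(f"frequency must be >= 0, got {self.frequency}")

    @property
    def omega(self) -> float:
        """Angular frequency 2*pi*frequency, rad/s."""
        return 2.0 * math.pi * self.frequency


#: Zero-frequency (pure conduction / DC) spec, handy for oracle gates.
DC = FrequencySpec(frequency=0.0)


class TissueTable:
    """A lookup table of :class:`TissueProperties` keyed by label."""

    def __init__(self, entries: Iterable[TissueProperties]):
        self._table: Dict[str, TissueProperties] = {}
        for e in entries:
            if e.label in self._table:
                raise ValueError(f"duplicate tissue label {e.label!r}")
            self._table[e.label] = e

    # -- construction ------------------------------------------------------

    @classmethod
    def default(cls) -> "TissueTable":
        """The packaged default property table (all ten canonical labels)."""
        with resources.files("ttfdose.data").joinpath("tissue_table.csv").open() as fh:
            table = cls.from_csv(fh)
        missing = set(TISSUE_LABELS) - set(table.labels)
        extra = set(table.labels) - set(TISSUE_LABELS)
        if missing or extra:  # pragma: no cover - packaging sanity check
            raise ValueError(f"default table malformed: missing={missing} extra={extra}")
        return table

    @classmethod
    def from_csv(cls, path_or_buf) -> "TissueTable":
        df = pd.read_csv(path_or_buf)
        required = {"label", "sigma_S_per_m", "eps_r"}
        if not required.issubset(df.columns):
            raise ValueError(f"tissue CSV needs columns {sorted(required)}, got {list(df.columns)}")
        return cls(
            TissueProperties(str(r.label), float(r.sigma_S_per_m), float(r.eps_r))
            for r in df.itertuples()
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame(
            {
                "label": [e.label for e in self._table.values()],
                "sigma_S_per_m": [e.sigma for e in self._table.values()],
                "eps_r": [e.eps_r for e in self._table.values()],
            }
        )
        df.to_csv(path, index=False)

    def override(self, label: str, sigma: float = None, eps_r: float = None) -> "TissueTable":
        """Return a copy with one tissue's properties replaced (validated)."""
        cur = self[label]
        new = TissueProperties(
            label,
            cur.sigma if sigma is None else sigma,
            cur.eps_r if eps_r is None else eps_r,
        )
        entries = [new if e.label == label else e for e in self._table.values()]
        return TissueTable(entries)

    # -- access ------------------------------------------------------------

    @property
    def labels(self):
        return tuple(self._table)

    def __getitem__(self, label: str) -> TissueProperties:
        try:
            return self._table[label]
        except KeyError:
            raise UnknownTissueError(label) from None

    def __contains__(self, label: str) -> bool:
        return label in self._table

    def __iter__(self):
        return iter(self._table.values())

    def sigma(self, label: str) -> float:
        return self[label].sigma

    def admittivity(self, label: str, freq: FrequencySpec) -> complex:
        """Complex admittivity of ``label`` at the working frequency."""
        return self[label].admittivity(freq)

    def admittivity_map(self, freq: FrequencySpec) -> Dict[str, complex]:
        return {e.label: e.admittivity(freq) for e in self}

    def sigma_map(self) -> Dict[str, float]:
        return {e.label: e.sigma for e in self}


def admittivity(props: TissueTable, label: str, freq: FrequencySpec) -> complex:
    """Module-level convenience wrapper for :meth:`TissueTable.admittivity`."""
    return props.admittivity(label, freq)
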