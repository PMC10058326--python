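"""Coarse-grained ligand-receptor toy systems and bundled reference tables.

The toy binding site is a radially symmetric Morse well of tunable depth:
rupture force under a ramped pull grows smoothly with depth, which gives a
synthetic affinity series the same monotone Fmax-vs-affinity structure the
downstream calibration assumes.  The module also ships the FABP4 reference
score tables used as the fixture/acceptance surface (CSV resources,
checksummed).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._units import RT_KCALMOL
from .affinity_stats import AffinityRecord

__all__ = [
    "PullSystem",
    "AffinitySeries",
    "FixtureTable",
    "make_pull_system",
    "make_affinity_series",
    "paper_fixture",
    "load_table",
    "FIXTURE_SHA256",
    "FixtureIntegrityError",
]

LN10 = math.log(10.0)

FIXTURE_SHA256 = {
    "table1": "7392f098ab938b9974a70562228451d88267bed396785997bd13fa5d00c9c57f",
    "table2": "44a7d250f695e5fb425aed3b58a2606fcd5160aef4c0bec4093832bc9e222263",
    "table7": "b60e53082605bba57db77cad4cc0424bd23d952d8ce3a7cac81ecd218cfc45e5",
}


class FixtureIntegrityError(RuntimeError):
    """A bundled reference table does not match its recorded checksum."""


@dataclass(frozen=True)
class PullSystem:
    """A point ligand bound in a radially symmetric Morse well.

    Potential: V(r) = well_depth * ((1 - exp(-r/well_width))^2 - 1), with r
    the ligand distance from ``receptor_center``.  The minimum sits at r = 0
    with V = -well_depth; the well is flat (exponentially so) a few widths
    out.  Energies in kcal/mol, lengths in angstrom, masses in daltons.
    """

    ligand_mass: float
    ligand_position: Tuple[float, float, float]
    receptor_center: Tuple[float, float, float]
    well_depth: float
    well_width: float
    egress_direction: Tuple[float, float, float]
    temperature: float = 298.0
    friction: float = 1.0  # 1/ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.well_depth <= 0:
            raise ValueError(f"well_depth must be > 0, got {self.well_depth}")
        if self.well_width <= 0:
            raise ValueError(f"well_width must be > 0, got {self.well_width}")
        if self.ligand_mass <= 0:
            raise ValueError(f"ligand_mass must be > 0, got {self.ligand_mass}")
        norm = math.sqrt(sum(c * c for c in self.egress_direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"egress_direction must be a unit vector, |d|={norm}")

    # -- toy potential -----------------------------------------------------
    def potential(self, position: Sequence[float]) -> float:
        """Well potential energy (kcal/mol) at a ligand position."""
        r = math.dist(position, self.receptor_center)
        e = math.exp(-r / self.well_width)
        return self.well_depth * ((1.0 - e) ** 2 - 1.0)

    def well_force(self, position: Sequence[float]) -> np.ndarray:
        """Force (kcal/mol/A) exerted by the well on the ligand."""
        d = np.asarray(position, dtype=float) - np.asarray(self.receptor_center)
        r = float(np.linalg.norm(d))
        if r == 0.0:
            return np.zeros(3)
        e = math.exp(-r / self.well_width)
        dvdr = 2.0 * self.well_depth / self.well_width * (1.0 - e) * e
        return -dvdr * d / r


@dataclass
class AffinitySeries:
    systems: List[PullSystem]
    true_ki: List[float]  # nM
    is_decoy: List[bool]

    def __post_init__(self) -> None:
        if not (len(self.systems) == len(self.true_ki) == len(self.is_decoy)):
            raise ValueError("systems, true_ki and is_decoy must have equal length")
        if any(k <= 0 for k in self.true_ki):
            raise ValueError("all true_ki must be positive")
        act = [s.well_depth for s, d in zip(self.systems, self.is_decoy) if not d]
        dec = [s.well_depth for s, d in zip(self.systems, self.is_decoy) if d]
        if act and dec and max(dec) >= min(act):
            raise ValueError("decoy well depths must lie strictly below all actives")

    @property
    def true_pki(self) -> List[float]:
        return [-math.log10(k * 1e-9) for k in self.true_ki]


@dataclass
class FixtureTable:
    rows: List[AffinityRecord]
    source: str


def make_pull_system(
    well_depth: float,
    ligand_mass: float,
    seed: int,
    *,
    well_width: float = 0.15,
    temperature: float = 298.0,
    friction: float = 1.0,
    egress_direction: Tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> PullSystem:
    """Build a toy system with the ligand resting at the well minimum."""
    if well_depth <= 0:
        raise ValueError(f"well_depth must be > 0, got {well_depth}")
    if ligand_mass <= 0:
        raise ValueError(f"ligand_mass must be > 0, got {ligand_mass}")
    return PullSystem(
        ligand_mass=ligand_mass,
        ligand_position=(0.0, 0.0, 0.0),
        receptor_center=(0.0, 0.0, 0.0),
        well_depth=well_depth,
        well_width=well_width,
        egress_direction=egress_direction,
        temperature=temperature,
        friction=friction,
        seed=seed,
    )


def pki_to_well_depth(pki: float, rt: float = RT_KCALMOL) -> float:
    """Map an affinity to a well depth via -dG = RT*ln(10)*pKi."""
    return rt * LN10 * pki


def make_affinity_series(
    n_active: int,
    n_decoy: int,
    pki_range: Tuple[float, float],
    noise_sd: float,
    seed: int,
    *,
    ligand_mass: float = 50.0,
    well_width: float = 0.15,
    temperature: float = 298.0,
    friction: float = 1.0,
) -> AffinitySeries:
    """Generate an active/decoy series with well depths monotone in pKi.

    Active pKi values are equally spaced on ``pki_range`` and perturbed by
    Gaussian noise of SD ``noise_sd`` (pKi units); decoy depths are drawn
    uniformly from (0.2, 0.8) times the weakest active depth.
    """
    if n_active < 2:
        raise ValueError(f"need at least 2 actives, got {n_active}")
    lo, hi = pki_range
    if lo == hi:
        raise ValueError("degenerate pki_range (lo == hi)")
    if not (3.0 < lo < 12.0 and 3.0 < hi < 12.0):
        raise ValueError(f"pki_range must lie within (3, 12), got {pki_range}")
    if n_decoy < 0:
        raise ValueError("n_decoy must be >= 0")

    rng = np.random.default_rng(seed)
    pki = np.linspace(lo, hi, n_active)
    if noise_sd > 0:
        pki = pki + rng.normal(0.0, noise_sd, size=n_active)
    depths = np.array([pki_to_well_depth(p) for p in pki])
    decoy_depths = rng.uniform(0.2, 0.8, size=n_decoy) * depths.min()

    systems: List[PullSystem] = []
    true_ki: List[float] = []
    flags: List[bool] = []
    for i, d in enumerate(list(depths) + list(decoy_depths)):
        is_decoy = i >= n_active
        implied_pki = d / (RT_KCALMOL * LN10)
        systems.append(
            make_pull_system(
                float(d),
                ligand_mass,
                seed=int(seed) * 10_000 + i,
                well_width=well_width,
                temperature=temperature,
                friction=friction,
            )
        )
        true_ki.append(10.0 ** (-implied_pki) * 1e9)
        flags.append(is_decoy)
    return AffinitySeries(systems=systems, true_ki=true_ki, is_decoy=flags)


# ---------------------------------------------------------------------------
# bundled reference tables

def _resource_bytes(source: str) -> bytes:
    return resources.files("smdrank").joinpath(f"data/{source}.csv").read_bytes()


def verify_fixture_checksums() -> None:
    """Raise :class:`FixtureIntegrityError` on any checksum mismatch."""
    for source, expected in FIXTURE_SHA256.items():
        got = hashlib.sha256(_resource_bytes(source)).hexdigest()
        if got != expected:
            raise FixtureIntegrityError(f"{source}.csv checksum mismatch: {got}")


def load_table(source: str) -> pd.DataFrame:
    """Load a bundled reference table ('table1', 'table2' or 'table7')."""
    if source not in FIXTURE_SHA256:
        raise ValueError(f"unknown fixture table {source!r}")
    import io

    return pd.read_csv(io.BytesIO(_resource_bytes(source)))


def paper_fixture(source: str) -> FixtureTable:
    """Bundled reference score tables as :class:`AffinityRecord` rows."""
    df = load_table(source)
    rows: List[AffinityRecord] = []
    if source == "table1":
        for _, r in df.iterrows():
            rows.append(
                AffinityRecord(
                    compound_id=str(int(r["compound"])),
                    pki=float(r["exp_pki"]),
                    autodock_pki=float(r["autodock_pki"]),
                    vina_pki=float(r["vina_pki"]),
                    mmpbsa_pki=float(r["mmpbsa_pki"]),
                    mmgbsa_pki=float(r["mmgbsa_pki"]),
                    total_smd_energy=float(r["total_smd_energy_kcalmol"]),
                    fmax=float(r["fmax_pn"]),
                )
            )
    elif source == "table2":
        for _, r in df.iterrows():
            rows.append(
                AffinityRecord(
                    compound_id=str(int(r["compound"])),
                    ki=float(r["ki_nm"]),
                    dg_bind=float(r["dg_from_ki"]),
                )
            )
    else:  # table7
        for _, r in df.iterrows():
            rows.append(
                AffinityRecord(
                    compound_id=str(int(r["compound"])),
                    total_smd_energy=float(r["total_smd_energy_kcalmol"]),
                    fmax=float(r["fmax_pn"]),
                    is_decoy=True,
                )
            )
    return FixtureTable(rows=rows, source=source)
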