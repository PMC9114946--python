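"""Stress-strain records: reading, preprocessing and synthetic generation.

Experimental records are two-column delimited text files (strain or stretch
against engineering stress in MPa).  Internally the abscissa is always the
stretch ``lam = 1 + strain``.  Two truncation rules prepare raw pulls for
fitting: cutting below the point of maximum stress gradient (used for
curves that continue to failure) and cutting at a fixed strain (10% by
default, used for high-resolution equine tendon data).

The synthetic generator evaluates the recruitment-model forward curve on a
stretch grid and adds IID mean-zero Gaussian noise, emulating a noisy
uniaxial tensile test with known ground-truth parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constitutive import MaterialParams, TriangularRecruitment, engineering_stress

__all__ = [
    "StressStrainRecord",
    "read_record",
    "write_record",
    "truncate_at_max_gradient",
    "truncate_at_strain",
    "generate_synthetic",
    "default_grid",
]

_MAX_GRADIENT_TAG = "truncated:max-gradient"


@dataclass(frozen=True)
class StressStrainRecord:
    """A uniaxial tensile record: stretch abscissa and engineering stress (MPa)."""

    stretch: np.ndarray
    stress: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        stretch = np.asarray(self.stretch, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        if stretch.ndim != 1 or stress.ndim != 1 or len(stretch) != len(stress):
            raise ValueError("stretch and stress must be 1-D vectors of equal length")
        if len(stretch) == 0:
            raise ValueError("record is empty")
        if np.any(np.diff(stretch) <= 0):
            raise ValueError("stretch must be strictly increasing")
        if stretch[0] < 1.0 - 1e-12:
            raise ValueError("stretch must be >= 1 (strain >= 0)")
        if not np.all(np.isfinite(stress)):
            raise ValueError("stress must be finite")
        object.__setattr__(self, "stretch", stretch)
        object.__setattr__(self, "stress", stress)

    def __len__(self) -> int:
        return len(self.stretch)

    @property
    def strain(self) -> np.ndarray:
        return self.stretch - 1.0

    @property
    def lam_max(self) -> float:
        return float(self.stretch[-1])

    def take(self, n: int, tag: str) -> "StressStrainRecord":
        """First ``n`` points with a provenance tag appended."""
        if n < 1:
            raise ValueError("truncation would leave an empty record")
        prov = f"{self.provenance}|{tag}" if self.provenance else tag
        return StressStrainRecord(self.stretch[:n].copy(), self.stress[:n].copy(), prov)


def read_record(path, dialect: str = "strain", delimiter=None) -> StressStrainRecord:
    """Read a two-column delimited text file into a canonical record.

    ``dialect`` names the first column's convention: ``"strain"`` (converted
    via lam = 1 + strain) or ``"stretch"``.  The delimiter is sniffed
    (comma / tab / whitespace) unless given; one header line is tolerated.
    """
    if dialect not in ("strain", "stretch"):
        raise ValueError("dialect must be 'strain' or 'stretch'")
    df = pd.read_csv(
        path,
        sep=delimiter,
        engine="python",
        header=None,
        comment="#",
        skip_blank_lines=True,
    )
    # Tolerate a single header line of column names.
    try:
        df = df.astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
        try:
            df = df.astype(float)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric rows in {path}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"expected two columns in {path}, found {df.shape[1]}")
    x = df.iloc[:, 0].to_numpy()
    stress = df.iloc[:, 1].to_numpy()
    stretch = 1.0 + x if dialect == "strain" else x
    return StressStrainRecord(stretch, stress, provenance=f"{path} ({dialect})")


def write_record(rec: StressStrainRecord, path, dialect: str = "stretch", delimiter: str = ",") -> None:
    """Write a record as delimited text with a one-line header."""
    if dialect == "stretch":
        first = rec.stretch
        name = "stretch"
    elif dialect == "strain":
        first = rec.strain
        name = "strain"
    else:
        raise ValueError("dialect must be 'strain' or 'stretch'")
    pd.DataFrame({name: first, "stress_mpa": rec.stress}).to_csv(
        path, sep=delimiter, index=False, float_format="%.17g"
    )


def truncate_at_max_gradient(rec: StressStrainRecord) -> StressStrainRecord:
    """Keep only the points strictly below the maximum stress gradient.

    The gradient is the forward difference dN/dlam; ties are broken to the
    earliest interval.  Applying the rule twice is a no-op (the provenance
    tag marks already-truncated records), since the cut is meant to remove
    the approach to failure once.
    """
    if _MAX_GRADIENT_TAG in rec.provenance:
        return rec
    if len(rec) < 3:
        raise ValueError("need at least 3 points to locate the maximum gradient")
    grads = np.diff(rec.stress) / np.diff(rec.stretch)
    cut = int(np.argmax(grads))
    return rec.take(cut, _MAX_GRADIENT_TAG)


def truncate_at_strain(rec: StressStrainRecord, max_strain: float = 0.10) -> StressStrainRecord:
    """Keep points with strain <= max_strain (boundary inclusive)."""
    keep = int(np.sum(rec.stretch <= 1.0 + max_strain + 1e-12))
    if keep == 0:
        raise ValueError(f"no points at or below {max_strain:.3g} strain")
    if keep == len(rec):
        return rec
    return rec.take(keep, f"truncated:strain<={max_strain:g}")


def default_grid(n: int = 200, max_strain: float = 0.10) -> np.ndarray:
    """Uniform stretch grid on [1, 1 + max_strain] used for synthetic data."""
    return np.linspace(1.0, 1.0 + max_strain, n)


def generate_synthetic(
    mat: MaterialParams,
    dist: TriangularRecruitment,
    grid: np.ndarray | None = None,
    noise_var: float = 0.01,
    seed=None,
) -> StressStrainRecord:
    """Noisy synthetic tensile test from the recruitment model.

    Stresses are the forward engineering-stress curve on ``grid`` plus IID
    N(0, noise_var) draws (noise_var in MPa^2); fully reproducible from
    ``seed``.
    """
    if noise_var < 0:
        raise ValueError("noise_var must be non-negative")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    clean = engineering_stress(mat, dist, grid)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(noise_var), size=grid.shape) if noise_var > 0 else 0.0
    prov = (
        f"synthetic(ncm={mat.ncm_modulus:g}, fib={mat.fibril_modulus:g}, "
        f"a={dist.a:g}, c={dist.c:g}, b={dist.b:g}, noise_var={noise_var:g}, seed={seed})"
    )
    return StressStrainRecord(grid, clean + noise, provenance=prov)
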