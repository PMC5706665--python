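"""Count-table and configuration I/O.

The on-disk interchange format is a comma-separated, UTF-8, header-mandatory
table with columns ``strain, treatment, day, tube, aliquot, density``; one
row per hemocytometer count, densities stored as integers on the 10^4
cells/ml scale.  Each distinct (strain, treatment) pair is an independent
fitting unit and is carried around in memory as an :class:`ObservationSet`.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .inference import MCMCConfig

__all__ = [
    "COLUMNS",
    "ObservationSet",
    "RunConfig",
    "read_count_table",
    "write_count_table",
    "split_series",
    "load_run_config",
]

logger = logging.getLogger("symgrowth.io")

COLUMNS = ("strain", "treatment", "day", "tube", "aliquot", "density")


@dataclass
class ObservationSet:
    """One strain x treatment count series.

    ``table`` has columns ``day`` (int), ``tube``/``aliquot`` (replicate
    labels) and ``density`` (non-negative int, 10^4 cells/ml scale).
    """

    strain: str
    treatment: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"day", "tube", "aliquot", "density"} - set(self.table.columns)
        if missing:
            raise ValueError(f"observation table missing columns: {sorted(missing)}")

    @property
    def days(self) -> np.ndarray:
        return self.table["day"].to_numpy(dtype=float)

    @property
    def densities(self) -> np.ndarray:
        return self.table["density"].to_numpy(dtype=np.int64)

    @property
    def n_obs(self) -> int:
        return len(self.table)

    def digest(self) -> str:
        """Stable sha256 of the series content, echoed into manifests."""
        canon = self.table[["day", "tube", "aliquot", "density"]].sort_values(
            ["day", "tube", "aliquot"]
        )
        payload = f"{self.strain}|{self.treatment}|" + canon.to_csv(index=False)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dataframe(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "treatment", self.treatment)
        out.insert(0, "strain", self.strain)
        return out[list(COLUMNS)]


def read_count_table(path) -> pd.DataFrame:
    """Read and validate a long-format count table.

    Non-integer densities (e.g. averaged replicate counts) are rounded
    half-to-even with a logged warning — the Poisson likelihood requires
    integer support.  Malformed rows are rejected with their file line
    numbers (header = line 1).
    """
    df = pd.read_csv(path)
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    df = df[list(COLUMNS)]

    bad_lines: list[int] = []
    day = pd.to_numeric(df["day"], errors="coerce")
    dens = pd.to_numeric(df["density"], errors="coerce")
    bad = (
        day.isna() | dens.isna()
        | (day < 0) | (day != day.round())
        | (dens < 0)
        | df["strain"].isna() | df["treatment"].isna()
    )
    if bad.any():
        # +2: header line plus 0-based index
        bad_lines = [int(i) + 2 for i in df.index[bad]]
        raise ValueError(f"{path}: malformed rows at lines {bad_lines}")

    rounded = np.rint(dens.to_numpy(dtype=float))  # half-to-even
    n_rounded = int(np.sum(rounded != dens.to_numpy(dtype=float)))
    if n_rounded:
        logger.warning(
            "%s: rounded %d non-integer densities half-to-even for Poisson support",
            path, n_rounded,
        )
    df["day"] = day.astype(np.int64)
    df["density"] = rounded.astype(np.int64)
    return df


def write_count_table(df: pd.DataFrame, path) -> None:
    df = df[list(COLUMNS)].copy()
    df["day"] = df["day"].astype(np.int64)
    df["density"] = df["density"].astype(np.int64)
    df.to_csv(path, index=False)


def split_series(df: pd.DataFrame) -> list[ObservationSet]:
    """Split a count table into independent (strain, treatment) series."""
    out = []
    for (strain, treatment), grp in df.groupby(["strain", "treatment"], sort=True):
        if grp.empty:
            continue
        out.append(
            ObservationSet(
                strain=str(strain),
                treatment=str(treatment),
                table=grp[["day", "tube", "aliquot", "density"]].reset_index(drop=True),
            )
        )
    return out


@dataclass
class RunConfig:
    """Pipeline configuration: MCMC layout plus run-level options."""

    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    scenarios: Optional[list[str]] = None      # None = full 5-strain x 4-treatment preset
    outdir: Path = Path("symgrowth_out")
    seed: int = 0
    prior_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    verbosity: str = "INFO"
    full: bool = False  # escalate to the original full-scale MCMC protocol

    def validate(self) -> None:
        self.mcmc.validate()
        for name, pair in self.prior_bounds.items():
            lo, hi = float(pair[0]), float(pair[1])
            if not lo < hi:
                raise ValueError(
                    f"prior bound override for {name} must have lower < upper, got {pair}"
                )


def load_run_config(path=None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    The YAML file may contain an ``mcmc`` block (MCMCConfig fields) and any
    top-level RunConfig field; keyword overrides win over the file.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})

    mcmc_kwargs = raw.pop("mcmc", {}) or {}
    if "seed" in raw and "seed" not in mcmc_kwargs:
        mcmc_kwargs["seed"] = int(raw["seed"])
    cfg = RunConfig(
        mcmc=MCMCConfig(**mcmc_kwargs),
        scenarios=raw.get("scenarios"),
        outdir=Path(raw.get("outdir", "symgrowth_out")),
        seed=int(raw.get("seed", 0)),
        prior_bounds={
            k: (float(v[0]), float(v[1]))
            for k, v in (raw.get("prior_bounds") or {}).items()
        },
        verbosity=str(raw.get("verbosity", "INFO")),
        full=bool(raw.get("full", False)),
    )
    cfg.validate()
    return cfg
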