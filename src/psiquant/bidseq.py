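"""Per-position deletion-rate quantification for BID-seq amplicons.

Bisulfite treatment converts pseudouridine into an adduct that registers
as a deletion during reverse transcription; the per-position deletion rate
in covering reads is the raw Ψ signal.  Effective pseudouridylation at a
site is the sample rate divided by the rate observed in a 100 % ΨTP
in-vitro-transcribed standard — the same normalization contract as the CMC
amplicon pipeline.

Input is a pre-extracted per-read record stream (read_id, position,
covered, deleted) rather than BAM, so the module is testable without an
aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cmc import effective_psi

__all__ = ["PileupProfile", "build_pileup", "effective_psi_at_site",
           "read_records", "InsufficientCoverageError"]

DEFAULT_MIN_COVERAGE = 100


class InsufficientCoverageError(ValueError):
    """Coverage at the requested site is below the no-call threshold."""


@dataclass
class PileupProfile:
    """Per-position coverage, deletion counts and deletion rates.

    ``deletion_rate`` is NaN where coverage is zero (undefined, not 0).
    """

    coverage: np.ndarray
    deletions: np.ndarray

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        self.deletions = np.asarray(self.deletions, dtype=np.int64)
        if self.coverage.shape != self.deletions.shape:
            raise ValueError("coverage and deletions must have equal length")
        if (self.deletions > self.coverage).any():
            raise ValueError("deletions exceed coverage at some position")

    @property
    def deletion_rate(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.coverage > 0,
                            self.deletions / np.maximum(self.coverage, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": np.arange(len(self.coverage)),
            "coverage": self.coverage,
            "deletions": self.deletions,
            "deletion_rate": self.deletion_rate,
        })


def read_records(path: str | Path) -> pd.DataFrame:
    """Load a TSV of per-read (read_id, position, covered, deleted) records."""
    df = pd.read_csv(path, sep="\t")
    required = {"read_id", "position", "covered", "deleted"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"record file missing columns: {sorted(missing)}")
    for col in ("covered", "deleted"):
        if df[col].dtype == object:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1", "t", "yes"))
        else:
            df[col] = df[col].astype(bool)
    return df


def build_pileup(records: pd.DataFrame, reference_length: int) -> PileupProfile:
    """Aggregate covering-read records into a per-position pileup.

    A deleted record implies a covered one; positions must lie within
    ``[0, reference_length)``.
    """
    pos = records["position"].to_numpy(dtype=np.int64)
    covered = records["covered"].to_numpy(dtype=bool)
    deleted = records["deleted"].to_numpy(dtype=bool)
    if (deleted & ~covered).any():
        raise ValueError("record marked deleted but not covered")
    if len(pos) and (pos.min() < 0 or pos.max() >= reference_length):
        raise ValueError(
            f"record position outside [0, {reference_length})"
        )
    coverage = np.zeros(reference_length, dtype=np.int64)
    deletions = np.zeros(reference_length, dtype=np.int64)
    np.add.at(coverage, pos[covered], 1)
    np.add.at(deletions, pos[deleted], 1)
    return PileupProfile(coverage=coverage, deletions=deletions)


def effective_psi_at_site(sample: PileupProfile, standard: PileupProfile,
                          site: int, min_coverage: int = DEFAULT_MIN_COVERAGE,
                          clamp: bool = False) -> float:
    """Effective Ψ fraction at one site: sample rate / 100 %-ΨTP standard rate.

    Sites with coverage below ``min_coverage`` in either profile are
    no-calls (raised, not reported as 0).
    """
    for name, prof in (("sample", sample), ("standard", standard)):
        if not (0 <= site < len(prof.coverage)):
            raise ValueError(f"site {site} outside {name} profile")
        if prof.coverage[site] < min_coverage:
            raise InsufficientCoverageError(
                f"{name} coverage {prof.coverage[site]} at site {site} "
                f"below min_coverage {min_coverage}"
            )
    sample_rate = float(sample.deletion_rate[site])
    standard_rate = float(standard.deletion_rate[site])
    value, _ = effective_psi(sample_rate, standard_rate, clamp=clamp)
    return value
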