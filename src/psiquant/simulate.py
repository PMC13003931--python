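"""Synthetic read and assay-table generators with known ground truth.

Every input the quantification pipeline consumes can be produced here under
an explicit stochastic model:

* CMC amplicon reads.  Each RNA molecule carries Ψ at the assayed site with
  probability ``psi_fraction`` (the true stoichiometry θ).  Reverse
  transcription over a CMC-adducted Ψ yields a single-base deletion with
  probability ``p_del_psi``; a non-deleted Ψ reads as a non-T base with
  probability ``p_mut_psi``.  Unmodified U deletes at a background rate
  ``p_del_u`` and otherwise reads T.  Molecules are tagged with a random
  UMI, amplified into a geometric number of PCR duplicates that share UMI
  and payload, and finally sequenced with a per-base substitution error.
* 100 % ΨTP / 0 % ΨTP standards: the same model with θ forced to 1 or 0,
  emulating in-vitro transcripts where every U is (or is not) Ψ.
* BID-seq covering-read records: reads tile a reference and register a
  deletion at each candidate Ψ position with probability
  θ·p_del_psi + (1−θ)·p_del_u.
* qPCR Cq tables, gel band tables, Sanger peak tables and performance /
  covariate tables with additive noise.

All generators take a mandatory seed and are bit-reproducible; there is no
global random state.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .targets import AmpliconTarget

__all__ = [
    "CmcSimParams",
    "TRUTH_LABELS",
    "simulate_cmc_reads",
    "simulate_standard",
    "simulate_bidseq_records",
    "simulate_cq_table",
    "simulate_assay_tables",
    "write_fastq",
    "write_params_sidecar",
    "CQ_BASELINE",
]

_BASES = np.array(list("ACGT"))
_NON_T = ["A", "C", "G"]

#: Per-molecule ground-truth labels; exclusive and exhaustive.
TRUTH_LABELS = (
    "psi_deleted",
    "psi_retained_mut",
    "psi_retained_T",
    "u_deleted",
    "u_retained",
)

# Cq for relative abundance 1.0; only Cq differences matter downstream.
CQ_BASELINE = 20.0


@dataclass(frozen=True)
class CmcSimParams:
    """Stochastic model parameters for CMC amplicon read simulation.

    Parameters
    ----------
    psi_fraction
        True Ψ stoichiometry θ at the assayed site, in [0, 1].
    p_del_psi
        Probability that a Ψ molecule yields a 1-nt deletion at the site.
    p_del_u
        Background deletion probability for an unmodified U.
    p_mut_psi
        Probability that a non-deleted Ψ reads as a non-T base.
    seq_error
        Per-base substitution error applied after PCR duplication.
    n_molecules
        Number of distinct RNA molecules (pre-PCR).
    dup_mean
        Mean PCR duplicates per molecule (geometric, support ≥ 1).
    umi_length, umi_offset
        UMI size and its 0-based position within the read.
    seed
        Mandatory RNG seed.
    """

    psi_fraction: float
    p_del_psi: float = 0.8
    p_del_u: float = 0.0
    p_mut_psi: float = 0.0
    seq_error: float = 0.0
    n_molecules: int = 10_000
    dup_mean: float = 1.0
    umi_length: int = 10
    umi_offset: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("psi_fraction", "p_del_psi", "p_del_u", "p_mut_psi", "seq_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.dup_mean < 1.0:
            raise ValueError("dup_mean must be >= 1")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if self.umi_offset < 0:
            raise ValueError("umi_offset must be >= 0")


def _random_umis(rng: np.random.Generator, n: int, length: int) -> list[str]:
    idx = rng.integers(0, 4, size=(n, length))
    return ["".join(_BASES[row]) for row in idx]


def _apply_seq_error(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0:
        return seq
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    chars = list(seq)
    for i in np.flatnonzero(mask):
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _molecule_payload(target: AmpliconTarget, label: str,
                      rng: np.random.Generator) -> str:
    """Amplicon payload (sense strand) for one molecule, given its fate."""
    ref = target.reference
    i = target.psi_index
    if label in ("psi_deleted", "u_deleted"):
        return ref[:i] + ref[i + 1 :]
    if label == "psi_retained_mut":
        return ref[:i] + _NON_T[rng.integers(0, 3)] + ref[i + 1 :]
    return ref  # psi_retained_T / u_retained: cDNA of U reads T


def _draw_labels(params: CmcSimParams, rng: np.random.Generator) -> np.ndarray:
    """Vectorised per-molecule fate draw; exclusive, exhaustive."""
    n = params.n_molecules
    is_psi = rng.random(n) < params.psi_fraction
    u1 = rng.random(n)
    u2 = rng.random(n)
    labels = np.empty(n, dtype=object)
    psi_del = is_psi & (u1 < params.p_del_psi)
    psi_mut = is_psi & ~psi_del & (u2 < params.p_mut_psi)
    psi_t = is_psi & ~psi_del & ~psi_mut
    u_del = ~is_psi & (u1 < params.p_del_u)
    u_ret = ~is_psi & ~u_del
    labels[psi_del] = "psi_deleted"
    labels[psi_mut] = "psi_retained_mut"
    labels[psi_t] = "psi_retained_T"
    labels[u_del] = "u_deleted"
    labels[u_ret] = "u_retained"
    return labels


def simulate_cmc_reads(
    target: AmpliconTarget, params: CmcSimParams
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate a CMC amplicon read set with per-molecule ground truth.

    Returns
    -------
    reads
        List of ``(read_id, sequence)`` in sequencing order.  Each read is
        the molecule payload with the UMI spliced in at ``umi_offset``;
        duplicates of one molecule share UMI and payload and differ only by
        sequencing error.
    truth
        One row per molecule: ``molecule_id``, ``umi``, ``label``,
        ``n_duplicates``.
    """
    rng = np.random.default_rng(params.seed)
    labels = _draw_labels(params, rng)
    umis = _random_umis(rng, params.n_molecules, params.umi_length)
    if params.dup_mean > 1.0:
        dup_counts = rng.geometric(1.0 / params.dup_mean, size=params.n_molecules)
    else:
        dup_counts = np.ones(params.n_molecules, dtype=int)

    k = params.umi_offset
    reads: list[tuple[str, str]] = []
    for mol_id in range(params.n_molecules):
        payload = _molecule_payload(target, labels[mol_id], rng)
        if len(payload) < k:
            raise ValueError("umi_offset exceeds payload length")
        tagged = payload[:k] + umis[mol_id] + payload[k:]
        for d in range(int(dup_counts[mol_id])):
            seq = _apply_seq_error(tagged, rng, params.seq_error)
            reads.append((f"mol{mol_id}_dup{d}", seq))

    truth = pd.DataFrame(
        {
            "molecule_id": np.arange(params.n_molecules),
            "umi": umis,
            "label": labels,
            "n_duplicates": dup_counts.astype(int),
        }
    )
    return reads, truth


def simulate_standard(
    target: AmpliconTarget,
    params: CmcSimParams,
    kind: Literal["psi100", "u100"],
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate a synthetic-standard read set (100 % or 0 % ΨTP).

    Identical to :func:`simulate_cmc_reads` with ``psi_fraction`` forced to
    1 (``psi100``) or 0 (``u100``); same seed gives byte-identical output
    to the corresponding θ=1 / θ=0 sample simulation.
    """
    if kind not in ("psi100", "u100"):
        raise ValueError(f"unknown standard kind {kind!r}")
    forced = dataclasses.replace(params, psi_fraction=1.0 if kind == "psi100" else 0.0)
    return simulate_cmc_reads(target, forced)


def simulate_bidseq_records(
    reference: str,
    psi_positions: Sequence[int],
    params: CmcSimParams,
    read_length: int | None = None,
) -> pd.DataFrame:
    """Simulate per-read coverage/deletion records for BID-seq quantification.

    Reads of ``read_length`` (default: full reference) tile the reference
    deterministically; each read covering a candidate Ψ position registers a
    deletion there with probability θ·p_del_psi + (1−θ)·p_del_u, drawn per
    molecule per site.  Records carry explicit (position, covered, deleted)
    triples so downstream quantification needs no alignment engine.
    Non-candidate covered positions are emitted as covered, never deleted.
    """
    reference = reference.upper()
    L = len(reference)
    for p in psi_positions:
        if not (0 <= p < L):
            raise ValueError(f"psi position {p} outside reference of length {L}")
        if reference[p] != "T":
            raise ValueError(f"reference base at psi position {p} is {reference[p]!r}, expected T/U")
    if read_length is None:
        read_length = L
    if not (1 <= read_length <= L):
        raise ValueError("read_length must be in [1, reference length]")

    rng = np.random.default_rng(params.seed)
    n = params.n_molecules
    n_starts = L - read_length + 1
    starts = np.arange(n) % n_starts  # deterministic tiling
    theta = params.psi_fraction

    rows: list[tuple[str, int, bool, bool]] = []
    psi_set = set(int(p) for p in psi_positions)
    for r in range(n):
        s = int(starts[r])
        rid = f"read{r}"
        for pos in range(s, s + read_length):
            if pos in psi_set:
                is_psi = rng.random() < theta
                p_del = params.p_del_psi if is_psi else params.p_del_u
                deleted = bool(rng.random() < p_del)
            else:
                deleted = False
            rows.append((rid, pos, True, deleted))
    return pd.DataFrame(rows, columns=["read_id", "position", "covered", "deleted"])


def simulate_cq_table(
    design: pd.DataFrame,
    noise_sd: float,
    seed: int,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate a long-form qPCR Cq table from true relative abundances.

    ``design`` columns: sample_id, fraction, gene, true_relative_abundance.
    Cq = 20 − log2(abundance) + Normal(0, noise_sd), one row per design row
    per replicate.  Perfect doubling per cycle is assumed, so halving the
    abundance raises Cq by exactly one cycle at zero noise.
    """
    ab = design["true_relative_abundance"].to_numpy(dtype=float)
    if (ab <= 0).any():
        bad = design.loc[ab <= 0]
        raise ValueError(f"non-positive abundance in design rows: {bad.index.tolist()}")
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(1, n_replicates + 1):
        noise = rng.normal(0.0, noise_sd, size=len(design)) if noise_sd > 0 else 0.0
        cq = CQ_BASELINE - np.log2(ab) + noise
        block = design[["sample_id", "fraction", "gene"]].copy()
        block["replicate"] = rep
        block["cq"] = cq
        out.append(block)
    return pd.concat(out, ignore_index=True)


def simulate_assay_tables(
    kind: Literal["gel_bands", "trace_peaks", "performance"],
    truth,
    seed: int,
) -> pd.DataFrame:
    """Simulate fixture tables for the assay-statistics formulas.

    gel_bands
        ``truth``: DataFrame (lane, isoform, molar_amount, length_bp) plus
        optional scalar column ``noise_sd``.  Band intensity is proportional
        to molar_amount × length (intercalating-dye mass signal) plus
        Gaussian noise, floored at 0.
    trace_peaks
        ``truth``: DataFrame (site, editing) with editing fraction e in
        [0, 1].  A/G peak heights proportional to (1−e, e); C/T peaks are
        small baseline noise.
    performance
        ``truth``: dict with keys n_genes, planted_r, ratio_mean, ratio_sd,
        (optional) exon_count_range.  Emits a per-gene table whose
        U7smOPT/cadRNA editing-efficiency ratio has the planted Pearson
        correlation with exon count; gene_length and export_rate are
        uncorrelated decoy covariates.
    """
    rng = np.random.default_rng(seed)
    if kind == "gel_bands":
        t = truth.copy()
        noise_sd = float(t["noise_sd"].iloc[0]) if "noise_sd" in t else 0.0
        intensity = t["molar_amount"].to_numpy(float) * t["length_bp"].to_numpy(float)
        if noise_sd > 0:
            intensity = intensity + rng.normal(0.0, noise_sd, size=len(t))
        t["intensity"] = np.clip(intensity, 0.0, None)
        return t[["lane", "isoform", "intensity", "length_bp"]]

    if kind == "trace_peaks":
        t = truth.copy()
        scale = 1000.0
        noise_sd = float(t["noise_sd"].iloc[0]) if "noise_sd" in t else 0.0
        e = t["editing"].to_numpy(float)
        a = (1.0 - e) * scale
        g = e * scale
        if noise_sd > 0:
            a = np.clip(a + rng.normal(0, noise_sd, len(t)), 0, None)
            g = np.clip(g + rng.normal(0, noise_sd, len(t)), 0, None)
        baseline = np.abs(rng.normal(0, noise_sd, (2, len(t)))) if noise_sd > 0 else np.zeros((2, len(t)))
        return pd.DataFrame(
            {"site": t["site"], "a": a, "c": baseline[0], "g": g, "t": baseline[1]}
        )

    if kind == "performance":
        n = int(truth["n_genes"])
        r = float(truth["planted_r"])
        ratio_mean = float(truth.get("ratio_mean", 1.5))
        ratio_sd = float(truth.get("ratio_sd", 0.3))
        lo, hi = truth.get("exon_count_range", (2, 80))
        exon_count = rng.integers(lo, hi + 1, size=n)
        zx = (exon_count - exon_count.mean()) / exon_count.std()
        eps = rng.normal(0.0, 1.0, size=n)
        ratio = ratio_mean + ratio_sd * (r * zx + np.sqrt(max(0.0, 1 - r * r)) * eps)
        ratio = np.clip(ratio, 0.05, None)
        mean_edit_cad = rng.uniform(0.1, 0.35, size=n)
        mean_edit_u7 = np.clip(ratio * mean_edit_cad, 0.0, 1.0)
        return pd.DataFrame(
            {
                "gene": [f"gene{i:02d}" for i in range(n)],
                "mean_edit_u7": mean_edit_u7,
                "mean_edit_cad": mean_edit_cad,
                "exon_count": exon_count,
                "gene_length": rng.uniform(5e3, 2e6, size=n),
                "export_rate": rng.uniform(0.1, 3.0, size=n),
            }
        )

    raise ValueError(f"unknown assay table kind {kind!r}")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path,
                quality_char: str = "I") -> int:
    """Write reads as 4-line FASTQ records with constant Phred+33 quality."""
    n = 0
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


def write_params_sidecar(params, seed_note: str | Path, path: str | Path) -> None:
    """Record simulation parameters and seed as a JSON sidecar."""
    if dataclasses.is_dataclass(params):
        payload = dataclasses.asdict(params)
    else:
        payload = dict(params)
    payload["note"] = str(seed_note)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
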