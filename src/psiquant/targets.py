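"""Amplicon locus definitions for targeted pseudouridine assays.

An :class:`AmpliconTarget` describes one assayed uridine: the sense-strand
amplicon reference, two 8-mer anchor sequences that flank a 3-nt window
(the NΨN context) whose central base is the candidate Ψ site.  Reads are
later classified by the gap observed between perfect anchor matches, so the
anchors must sit immediately against the triplet in the reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["AmpliconTarget", "TargetValidationError", "load_targets", "make_target"]

ANCHOR_LEN = 8

_VALID_BASES = set("ACGT")


class TargetValidationError(ValueError):
    """A target definition violates a structural invariant.

    Carries the locus name and every violation found, not just the first.
    """

    def __init__(self, locus_name: str, problems: list[str]):
        self.locus_name = locus_name
        self.problems = list(problems)
        msg = "; ".join(problems)
        super().__init__(f"target {locus_name!r}: {msg}")


@dataclass(frozen=True)
class AmpliconTarget:
    """One assayed NΨN locus on a sequenced amplicon.

    Attributes
    ----------
    locus_name
        Identifier used in reports and error messages.
    reference
        Sense-orientation nucleotide sequence of the amplicon (DNA alphabet;
        the cDNA of an unmodified U reads T).
    anchor_up, anchor_down
        The exact 8-mers immediately upstream / downstream of the triplet.
    center_triplet
        The 3-nt NΨN window; the middle base is the assayed uridine.
    psi_index
        0-based index of the middle triplet base in ``reference``.
    """

    locus_name: str
    reference: str
    anchor_up: str
    anchor_down: str
    center_triplet: str
    psi_index: int

    def __post_init__(self) -> None:
        problems: list[str] = []
        ref = self.reference.upper()
        up, down, trip = (
            self.anchor_up.upper(),
            self.anchor_down.upper(),
            self.center_triplet.upper(),
        )
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "anchor_up", up)
        object.__setattr__(self, "anchor_down", down)
        object.__setattr__(self, "center_triplet", trip)

        for name, seq in (("reference", ref), ("anchor_up", up),
                          ("anchor_down", down), ("center_triplet", trip)):
            if not set(seq) <= _VALID_BASES:
                problems.append(f"{name} contains non-ACGT characters")
        if len(up) != ANCHOR_LEN:
            problems.append(f"anchor_up length {len(up)} != {ANCHOR_LEN}")
        if len(down) != ANCHOR_LEN:
            problems.append(f"anchor_down length {len(down)} != {ANCHOR_LEN}")
        if len(trip) != 3:
            problems.append(f"center_triplet length {len(trip)} != 3")
        if problems:
            raise TargetValidationError(self.locus_name, problems)

        i = self.psi_index
        if not (0 <= i < len(ref)):
            problems.append(f"psi_index {i} outside reference of length {len(ref)}")
            raise TargetValidationError(self.locus_name, problems)
        if ref[i] != "T":
            problems.append(f"reference base at psi_index is {ref[i]!r}, expected T")
        if ref[i - 1 : i + 2] != trip:
            problems.append(
                f"center_triplet {trip!r} does not match reference context "
                f"{ref[i - 1:i + 2]!r} at psi_index"
            )
        # anchors must sit immediately against the triplet (hence cannot
        # overlap it or each other)
        up_start = i - 1 - ANCHOR_LEN
        down_start = i + 2
        if up_start < 0 or ref[up_start : i - 1] != up:
            problems.append("anchor_up does not immediately precede center_triplet")
        if ref[down_start : down_start + ANCHOR_LEN] != down:
            problems.append("anchor_down does not immediately follow center_triplet")
        if problems:
            raise TargetValidationError(self.locus_name, problems)

    @property
    def amplicon_core(self) -> str:
        """anchor_up + center_triplet + anchor_down, the matched region."""
        return self.anchor_up + self.center_triplet + self.anchor_down


def make_target(locus_name: str, flank5: str, triplet: str, anchor_up: str,
                anchor_down: str, flank3: str) -> AmpliconTarget:
    """Assemble a valid target from its parts (convenience constructor)."""
    reference = flank5 + anchor_up + triplet + anchor_down + flank3
    psi_index = len(flank5) + ANCHOR_LEN + 1
    return AmpliconTarget(
        locus_name=locus_name,
        reference=reference,
        anchor_up=anchor_up,
        anchor_down=anchor_down,
        center_triplet=triplet,
        psi_index=psi_index,
    )


def load_targets(path: str | Path) -> list[AmpliconTarget]:
    """Parse a target definition file (TSV or JSON) and validate every locus.

    TSV columns: locus_name, reference, anchor_up, anchor_down,
    center_triplet, psi_index (0-based).  JSON: a list of objects with the
    same keys.  All violations across all loci are collected and reported
    together in a single :class:`TargetValidationError`-derived message.
    """
    path = Path(path)
    text = path.read_text()
    rows: list[dict]
    if path.suffix.lower() == ".json":
        rows = json.loads(text)
    else:
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        header = lines[0].split("\t")
        rows = [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]

    targets: list[AmpliconTarget] = []
    failures: list[str] = []
    for row in rows:
        try:
            targets.append(
                AmpliconTarget(
                    locus_name=str(row["locus_name"]),
                    reference=str(row["reference"]),
                    anchor_up=str(row["anchor_up"]),
                    anchor_down=str(row["anchor_down"]),
                    center_triplet=str(row["center_triplet"]),
                    psi_index=int(row["psi_index"]),
                )
            )
        except TargetValidationError as exc:
            failures.append(str(exc))
        except (KeyError, ValueError) as exc:
            failures.append(f"target row {row.get('locus_name', '?')!r}: {exc}")
    if failures:
        raise TargetValidationError(path.name, failures)
    return targets
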