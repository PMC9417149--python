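"""Dystrophin exon model and reading-frame arithmetic.

The dystrophin gene (*DMD*, Xp21.2) has 79 exons; the full-length muscle
transcript Dp427m encodes a 3,685-residue protein from an 11,058 nt coding
sequence (stop codon included).  Whether an exon-level deletion or
duplication preserves the translational reading frame is determined purely
by the summed coding length of the affected exons: a multiple of 3 leaves
the downstream frame intact (in-frame, typically the milder Becker
phenotype), anything else shifts it (out-of-frame, typically Duchenne).

Events touching the first or last exon are reported as ``indeterminate``:
the mod-3 argument presumes an intact translation start and a downstream
frame left to disrupt, and neither holds at the transcript ends.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "N_EXONS",
    "ExonTable",
    "ExonTableFormatError",
    "FrameStatus",
    "VariantEvent",
    "VariantKind",
    "coding_span_length",
    "frame_status",
    "load_exon_table",
]

N_EXONS = 79


class ExonTableFormatError(ValueError):
    """Raised when an exon table file violates the table invariants."""


class VariantKind(str, enum.Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"


class FrameStatus(str, enum.Enum):
    IN_FRAME = "in_frame"
    OUT_OF_FRAME = "out_of_frame"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class VariantEvent:
    """A contiguous exon-level deletion or duplication, 1-based inclusive.

    Non-contiguous (multi-interval) events are not representable; evaluate
    each interval separately.
    """

    kind: VariantKind
    start_exon: int
    end_exon: int

    def __post_init__(self) -> None:
        kind = VariantKind(self.kind)
        object.__setattr__(self, "kind", kind)
        for name in ("start_exon", "end_exon"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise ValueError(f"{name} must be an integer, got {value!r}")
            if not 1 <= value <= N_EXONS:
                raise ValueError(f"{name}={value} outside exon range 1..{N_EXONS}")
        if self.start_exon > self.end_exon:
            raise ValueError(
                f"start_exon {self.start_exon} > end_exon {self.end_exon}; "
                "exon ranges are ascending"
            )

    @property
    def n_exons(self) -> int:
        return self.end_exon - self.start_exon + 1


@dataclass(frozen=True)
class ExonTable:
    """Per-exon coding lengths (nt) of a 79-exon dystrophin transcript.

    ``lengths[i]`` is the coding length of exon ``i + 1``.  The packaged
    default is the Dp427m muscle isoform with the stop codon counted in
    exon 79 and UTRs excluded, so the lengths sum to the full CDS.
    """

    transcript_id: str
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.lengths) != N_EXONS:
            raise ExonTableFormatError(
                f"expected {N_EXONS} exons, got {len(self.lengths)}"
            )
        for i, length in enumerate(self.lengths, start=1):
            if not isinstance(length, (int, np.integer)) or length < 1:
                raise ExonTableFormatError(
                    f"exon {i}: coding_length_nt must be a positive integer, "
                    f"got {length!r}"
                )
        object.__setattr__(self, "lengths", tuple(int(x) for x in self.lengths))
        # cumulative[i] = total coding nt of exons 1..i
        cumulative = np.concatenate([[0], np.cumsum(self.lengths)])
        object.__setattr__(self, "_cumulative", cumulative)

    @property
    def total_coding_nt(self) -> int:
        return int(self._cumulative[-1])

    def coding_length(self, exon: int) -> int:
        if not 1 <= exon <= N_EXONS:
            raise ValueError(f"exon index {exon} outside 1..{N_EXONS}")
        return self.lengths[exon - 1]


def load_exon_table(path: str | Path | None = None) -> ExonTable:
    """Read an exon table TSV; ``None`` loads the packaged Dp427m table.

    The file has columns ``exon_index`` and ``coding_length_nt`` and ``#``
    comment lines carrying ``key: value`` metadata.  A ``total_coding_nt``
    metadata entry, when present, is asserted against the column sum.
    """
    if path is None:
        ref = resources.files("dmdframe") / "data" / "dp427m_exons.tsv"
        text = ref.read_text(encoding="utf-8")
        source = "packaged dp427m_exons.tsv"
    else:
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        source = str(path)

    meta: dict[str, str] = {}
    rows: dict[int, int] = {}
    header: list[str] | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if fields[:2] != ["exon_index", "coding_length_nt"]:
                raise ExonTableFormatError(
                    f"{source}: expected columns exon_index, coding_length_nt; "
                    f"got {fields!r}"
                )
            continue
        try:
            idx, length = int(fields[0]), int(fields[1])
        except (ValueError, IndexError) as exc:
            raise ExonTableFormatError(f"{source}, line {lineno}: {line!r}") from exc
        if not 1 <= idx <= N_EXONS:
            raise ExonTableFormatError(
                f"{source}, line {lineno}: exon index {idx} outside 1..{N_EXONS}"
            )
        if idx in rows:
            raise ExonTableFormatError(
                f"{source}, line {lineno}: duplicate exon index {idx}"
            )
        if length < 1:
            raise ExonTableFormatError(
                f"{source}, line {lineno}: non-positive coding length {length}"
            )
        rows[idx] = length

    missing = sorted(set(range(1, N_EXONS + 1)) - rows.keys())
    if missing:
        raise ExonTableFormatError(
            f"{source}: duplicate/missing exon index — missing {missing}"
        )
    table = ExonTable(
        transcript_id=meta.get("transcript_id", source),
        lengths=tuple(rows[i] for i in range(1, N_EXONS + 1)),
    )
    if "total_coding_nt" in meta:
        documented = int(meta["total_coding_nt"])
        if table.total_coding_nt != documented:
            raise ExonTableFormatError(
                f"{source}: lengths sum to {table.total_coding_nt}, header "
                f"documents {documented}"
            )
    return table


def coding_span_length(table: ExonTable, start_exon: int, end_exon: int) -> int:
    """Summed coding length (nt) of exons ``start_exon..end_exon`` inclusive."""
    if not (1 <= start_exon <= end_exon <= N_EXONS):
        raise ValueError(
            f"invalid exon span {start_exon}..{end_exon} (need 1 <= start <= end <= {N_EXONS})"
        )
    return int(table._cumulative[end_exon] - table._cumulative[start_exon - 1])


def frame_status(table: ExonTable, event: VariantEvent) -> FrameStatus:
    """Reading-frame status of an exon-level deletion or duplication.

    Deletions and duplications of the same range shift the downstream frame
    by -L and +L nucleotides respectively, so both are in-frame exactly when
    L mod 3 == 0.  Ranges touching exon 1 (translation start) or exon 79
    (transcript end) are ``indeterminate``: the rule does not apply there.
    """
    if event.start_exon == 1 or event.end_exon == N_EXONS:
        return FrameStatus.INDETERMINATE
    span = coding_span_length(table, event.start_exon, event.end_exon)
    return FrameStatus.IN_FRAME if span % 3 == 0 else FrameStatus.OUT_OF_FRAME
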