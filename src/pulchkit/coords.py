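"""Zero-free promoter coordinate arithmetic and probe maps.

Promoter biology numbers positions without a zero: ... -2, -1, +1, +2 ...
where +1 is the transcription start site (TSS) or, for probe definitions,
the first base of the ATG start codon.  All interval arithmetic here is
performed in that zero-free system, so the interval -14..+45 spans 59
positions, not 60.

A :class:`ProbeMap` describes a 5'-end-labeled DNA probe: fragment size
``s`` produced by nuclease cleavage corresponds to the ``s``-th probe
position counted from the labeled end.  Deletion probes carry a coordinate
gap so that fragment sizes map across the deleted segment onto the original
promoter coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class CoordinateError(ValueError):
    """A position or interval is invalid in zero-free coordinates."""


def to_ordinal(pos: int) -> int:
    """Map a zero-free coordinate onto consecutive integers.

    ... -2 -> -2, -1 -> -1, +1 -> 0, +2 -> 1 ...  Position 0 is illegal.
    """
    if pos == 0:
        raise CoordinateError("position 0 does not exist in zero-free coordinates")
    return pos if pos < 0 else pos - 1


def from_ordinal(n: int) -> int:
    """Inverse of :func:`to_ordinal`."""
    return n if n < 0 else n + 1


def advance(pos: int, steps: int) -> int:
    """Move ``steps`` positions downstream (negative = upstream)."""
    return from_ordinal(to_ordinal(pos) + steps)


def span_length(start: int, end: int) -> int:
    """Number of positions in the zero-free interval ``start..end`` inclusive."""
    n = to_ordinal(end) - to_ordinal(start) + 1
    if n < 1:
        raise CoordinateError(f"empty interval {start}..{end}")
    return n


@dataclass(frozen=True)
class ProbeMap:
    """A 5'-labeled probe in promoter coordinates.

    Parameters
    ----------
    label_end_atg:
        Zero-free coordinate, relative to the ATG start codon, of the
        labeled 5' end (the small-fragment end).
    probe_len:
        Probe length in bp.
    tss_offset_atg:
        Zero-free coordinate of the TSS relative to the ATG.  Must be
        supplied by the user; it is not derivable from the probe itself.
    deletion_ordinals:
        Optional half-open ordinal interval (start, stop) of deleted
        positions, in ATG-relative ordinals.  Internal bookkeeping for
        deletion probes; use :func:`build_deletion_probe` to construct.
    """

    label_end_atg: int
    probe_len: int
    tss_offset_atg: int
    deletion_ordinals: tuple[int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.probe_len < 1:
            raise CoordinateError("probe_len must be >= 1")
        to_ordinal(self.label_end_atg)
        to_ordinal(self.tss_offset_atg)

    # -- size <-> position -------------------------------------------------

    def position_atg_of_size(self, size: int) -> int:
        """ATG-relative coordinate of the cleavage position giving fragment ``size``."""
        if not 1 <= size <= self.probe_len:
            raise CoordinateError(
                f"fragment size {size} outside probe of length {self.probe_len}"
            )
        n = to_ordinal(self.label_end_atg) + (size - 1)
        if self.deletion_ordinals is not None:
            gap_start, gap_stop = self.deletion_ordinals
            if n >= gap_start:
                n += gap_stop - gap_start
        return from_ordinal(n)

    def position_tss_of_size(self, size: int) -> int:
        """TSS-relative coordinate of the position giving fragment ``size``."""
        return self.rebase_to_tss(self.position_atg_of_size(size))

    def size_of_position_tss(self, pos_tss: int) -> int:
        """Fragment size whose cleavage position is ``pos_tss``; inverse of
        :meth:`position_tss_of_size`."""
        n = to_ordinal(self.tss_offset_atg) + to_ordinal(pos_tss)
        if self.deletion_ordinals is not None:
            gap_start, gap_stop = self.deletion_ordinals
            if gap_start <= n < gap_stop:
                raise CoordinateError(f"position {pos_tss} lies in the deleted segment")
            if n >= gap_stop:
                n -= gap_stop - gap_start
        size = n - to_ordinal(self.label_end_atg) + 1
        if not 1 <= size <= self.probe_len:
            raise CoordinateError(f"position {pos_tss} outside probe")
        return size

    def rebase_to_tss(self, pos_atg: int) -> int:
        """Convert an ATG-relative coordinate to a TSS-relative one (TSS = +1)."""
        return from_ordinal(to_ordinal(pos_atg) - to_ordinal(self.tss_offset_atg))

    def covers_tss_window(self, start_tss: int, end_tss: int) -> bool:
        """True if every position of the zero-free window lies on the probe."""
        try:
            self.size_of_position_tss(start_tss)
            self.size_of_position_tss(end_tss)
        except CoordinateError:
            return False
        return True


def to_promoter_coords(size_bp: float, probe: ProbeMap) -> int:
    """Map a calibrated fragment size (bp, possibly fractional) to a
    TSS-relative promoter position.

    The size is rounded to the nearest integer before mapping; sizes that
    round outside ``1..probe_len`` raise :class:`CoordinateError`.
    """
    size = int(round(size_bp))
    return probe.position_tss_of_size(size)


def build_deletion_probe(probe: ProbeMap, del_start_tss: int, del_end_tss: int) -> ProbeMap:
    """Derive the probe obtained by deleting the zero-free TSS-anchored
    interval ``del_start_tss..del_end_tss`` from ``probe``.

    The returned probe is shorter by the zero-free span of the interval and
    records a coordinate gap so fragment sizes on the deletion probe still
    map to original promoter coordinates.
    """
    if probe.deletion_ordinals is not None:
        raise CoordinateError("probe already carries a deletion")
    if not probe.covers_tss_window(del_start_tss, del_end_tss):
        raise CoordinateError(
            f"deletion interval {del_start_tss}..{del_end_tss} not inside probe"
        )
    removed = span_length(del_start_tss, del_end_tss)
    gap_start = to_ordinal(probe.tss_offset_atg) + to_ordinal(del_start_tss)
    return ProbeMap(
        label_end_atg=probe.label_end_atg,
        probe_len=probe.probe_len - removed,
        tss_offset_atg=probe.tss_offset_atg,
        deletion_ordinals=(gap_start, gap_start + removed),
    )
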