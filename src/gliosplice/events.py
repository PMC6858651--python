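"""Splicing-event identities.

Splicing events are named ``SYMBOL|as_id|TYPE[|exon_label]``, e.g.
``KIF4A|10001|AT|exon32``.  The ``|`` separator is deliberate: gene symbols
may legally contain ``-`` and ``_``.  ``TYPE`` is one of the seven
TCGASpliceSeq splice categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The seven splice-event categories: exon skip, retained intron, alternate
#: promoter, alternate terminator, alternate donor, alternate acceptor and
#: mutually exclusive exons.
SPLICE_TYPES: tuple[str, ...] = ("ES", "RI", "AP", "AT", "AD", "AA", "ME")


class EventParseError(ValueError):
    """Raised when an event-id string cannot be parsed."""


@dataclass(frozen=True, order=True)
class SpliceEvent:
    """Identity of a single alternative-splicing event.

    Parameters
    ----------
    symbol : str
        Gene symbol the event belongs to.
    as_id : int
        Integer event identifier (unique per gene in TCGASpliceSeq).
    splice_type : str
        One of :data:`SPLICE_TYPES`.
    exon_label : str, optional
        Free-text exon descriptor such as ``"exon32"``; empty if unknown.
    """

    symbol: str
    as_id: int
    splice_type: str
    exon_label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.splice_type not in SPLICE_TYPES:
            raise EventParseError(
                f"unknown splice type {self.splice_type!r}; "
                f"legal codes are {', '.join(SPLICE_TYPES)}"
            )

    @property
    def event_id(self) -> str:
        """Canonical string form ``SYMBOL|as_id|TYPE[|exon_label]``."""
        base = f"{self.symbol}|{self.as_id}|{self.splice_type}"
        return f"{base}|{self.exon_label}" if self.exon_label else base

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.event_id


def parse_event_id(raw: str) -> SpliceEvent:
    """Parse ``SYMBOL|as_id|TYPE[|exon_label]`` into a :class:`SpliceEvent`.

    >>> parse_event_id("KIF4A|10001|AT|exon32")
    SpliceEvent(symbol='KIF4A', as_id=10001, splice_type='AT', exon_label='exon32')
    """
    parts = str(raw).strip().split("|")
    if len(parts) not in (3, 4):
        raise EventParseError(
            f"cannot parse event id {raw!r}: expected "
            "'SYMBOL|as_id|TYPE' or 'SYMBOL|as_id|TYPE|exon_label'"
        )
    symbol, as_id_s, splice_type = parts[0], parts[1], parts[2]
    exon_label = parts[3] if len(parts) == 4 else ""
    if not symbol:
        raise EventParseError(f"empty gene symbol in event id {raw!r}")
    try:
        as_id = int(as_id_s)
    except ValueError as exc:
        raise EventParseError(
            f"non-integer as_id {as_id_s!r} in event id {raw!r}"
        ) from exc
    return SpliceEvent(symbol=symbol, as_id=as_id, splice_type=splice_type,
                       exon_label=exon_label)
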