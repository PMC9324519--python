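"""Pathway collections with signed activator/repressor gene roles.

Each pathway member carries an activator/repressor role (ARR) in
{-1, -0.5, 0, 0.5, 1}: -1 repressor, -0.5 probable repressor, 0 neutral or
ambivalent, 0.5 probable activator, 1 activator. Collections are stored in a
role-extended GMT dialect ("GMTX"): one pathway per line,

    pathway_id<TAB>class<TAB>gene:role<TAB>gene:role...

with class one of ``signaling``/``metabolic``. Plain GMT (second column a
free-text description, members bare gene symbols) is accepted for unsigned
sets; every role then defaults to +1 with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ParseError, PathwayUnmeasured

logger = logging.getLogger(__name__)

LEGAL_ROLES = (-1.0, -0.5, 0.0, 0.5, 1.0)
PATHWAY_CLASSES = ("signaling", "metabolic")


@dataclass(frozen=True)
class Pathway:
    """A named gene set whose members carry signed roles."""

    id: str
    klass: str
    members: dict[str, float]
    name: str = ""
    #: member count before any restriction to a measured gene universe
    original_size: int | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.id!r}: empty member list")
        bad = {g: r for g, r in self.members.items() if r not in LEGAL_ROLES}
        if bad:
            raise ValueError(f"pathway {self.id!r}: illegal ARR values {bad}")
        if self.klass not in PATHWAY_CLASSES:
            raise ValueError(f"pathway {self.id!r}: unknown class {self.klass!r}")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PathwayCollection:
    pathways: list[Pathway]
    source: str = ""
    _by_id: dict[str, Pathway] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for p in self.pathways:
            if p.id in self._by_id:
                raise ValueError(f"duplicate pathway id {p.id!r}")
            self._by_id[p.id] = p

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._by_id[pathway_id]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id


def _parse_role(token: str, lineno: int) -> float:
    if token not in {"-1", "-0.5", "0", "0.5", "1"}:
        raise ParseError(f"illegal role token {token!r}", line=lineno)
    return float(token)


def read_collection(path) -> PathwayCollection:
    """Read a GMTX (or plain GMT) pathway collection."""
    pathways: list[Pathway] = []
    plain_gmt_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("empty member list", line=lineno)
            pid, klass_or_desc = parts[0], parts[1]
            member_tokens = [t for t in parts[2:] if t]
            if not member_tokens:
                raise ParseError("empty member list", line=lineno)
            signed = all(":" in t for t in member_tokens)
            members: dict[str, float] = {}
            if signed:
                if klass_or_desc not in PATHWAY_CLASSES:
                    raise ParseError(
                        f"unknown pathway class {klass_or_desc!r}", line=lineno
                    )
                klass = klass_or_desc
                for tok in member_tokens:
                    gene, _, role = tok.rpartition(":")
                    if gene in members:
                        raise ParseError(f"duplicate gene {gene!r}", line=lineno)
                    members[gene] = _parse_role(role, lineno)
            else:
                if any(":" in t for t in member_tokens):
                    raise ParseError("mixed signed and unsigned member tokens", line=lineno)
                plain_gmt_lines += 1
                klass = klass_or_desc if klass_or_desc in PATHWAY_CLASSES else "signaling"
                for gene in member_tokens:
                    if gene in members:
                        raise ParseError(f"duplicate gene {gene!r}", line=lineno)
                    members[gene] = 1.0
            try:
                pathways.append(Pathway(id=pid, klass=klass, members=members))
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from None
    if plain_gmt_lines:
        logger.warning(
            "%d plain GMT lines read as unsigned sets (all roles +1)", plain_gmt_lines
        )
    try:
        return PathwayCollection(pathways, source=str(path))
    except ValueError as exc:
        raise ParseError(str(exc)) from None


def _fmt_role(role: float) -> str:
    return str(int(role)) if role == int(role) else str(role)


def write_collection(coll: PathwayCollection, path) -> None:
    """Write a collection in GMTX; read_collection round-trips it exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in coll:
            toks = "\t".join(f"{g}:{_fmt_role(r)}" for g, r in p.members.items())
            fh.write(f"{p.id}\t{p.klass}\t{toks}\n")


def restrict_to_measured(p: Pathway, genes) -> Pathway:
    """Sub-pathway of members present in ``genes``.

    Raises :class:`PathwayUnmeasured` when no member is measured, so batch
    callers can skip the pathway and record the reason. The returned pathway
    remembers the original member count for reporting.
    """
    measured = {g: r for g, r in p.members.items() if g in set(genes)}
    if not measured:
        raise PathwayUnmeasured(p.id)
    return Pathway(
        id=p.id,
        klass=p.klass,
        members=measured,
        name=p.name,
        original_size=p.original_size if p.original_size is not None else len(p),
    )
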