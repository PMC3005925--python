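"""GenBank and FASTA round-trip I/O for duplex fragments.

GenBank is the interchange format for annotated plasmids (features plus
circular topology); FASTA serves bare fragments. Sticky ends and topology,
which neither format models natively, travel as bracketed tokens in the
record description, e.g.::

    [topology=linear] [left_end=five_prime:GATC:top] [right_end=five_prime:CGCG:bottom]

Reading then writing is the identity on sequence, topology, sticky ends
and features. Records missing the toolkit's role qualifiers load with the
unknown features logged and attached as notes, never silently dropped.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .seqcore import (
    BLUNT,
    CIRCULAR,
    FEATURE_ROLES,
    LINEAR,
    DuplexFragment,
    Feature,
    StickyEnd,
)

log = logging.getLogger(__name__)

_END_TOKEN = re.compile(r"\[(left_end|right_end)=(\w+):([ACGT]*):(\w+)\]")
_TOPO_TOKEN = re.compile(r"\[topology=(circular|linear)\]")

_META_PREFIX = "og_"


def _description(molecule: DuplexFragment) -> str:
    parts = [f"[topology={molecule.topology}]"]
    if not molecule.is_circular:
        for side, end in (("left_end", molecule.left_end), ("right_end", molecule.right_end)):
            parts.append(f"[{side}={end.kind}:{end.overhang}:{end.strand}]")
    return " ".join(parts)


def _parse_ends(description: str) -> tuple[str, StickyEnd | None, StickyEnd | None]:
    topo_m = _TOPO_TOKEN.search(description or "")
    topology = topo_m.group(1) if topo_m else LINEAR
    if topology == CIRCULAR:
        return CIRCULAR, None, None
    ends = {"left_end": BLUNT, "right_end": BLUNT}
    for m in _END_TOKEN.finditer(description or ""):
        side, kind, overhang, strand = m.groups()
        ends[side] = BLUNT if kind == "blunt" else StickyEnd(kind, overhang, strand)
    return LINEAR, ends["left_end"], ends["right_end"]


def to_seqrecord(molecule: DuplexFragment) -> SeqRecord:
    rec = SeqRecord(
        Seq(molecule.top),
        id=molecule.name or "fragment",
        name=(molecule.name or "fragment")[:16].replace(" ", "_"),
        description=_description(molecule),
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = molecule.topology
    for f in molecule.features:
        quals = {"label": [f.label], "role": [f.role]}
        for k, v in f.meta.items():
            quals[_META_PREFIX + k] = [str(v)]
        rec.features.append(
            SeqFeature(FeatureLocation(f.start, f.end), type="misc_feature", qualifiers=quals)
        )
    return rec


def from_seqrecord(rec: SeqRecord) -> DuplexFragment:
    topology = rec.annotations.get("topology")
    if topology not in (CIRCULAR, LINEAR):
        topology, left, right = _parse_ends(rec.description)
    elif topology == CIRCULAR:
        left = right = None
    else:
        _, left, right = _parse_ends(rec.description)
    feats = []
    notes = []
    for sf in rec.features:
        if sf.type != "misc_feature":
            continue
        label = (sf.qualifiers.get("label") or [""])[0]
        role = (sf.qualifiers.get("role") or [""])[0]
        if role not in FEATURE_ROLES:
            msg = f"feature {label or sf.type!r} at {sf.location} lacks a known role qualifier"
            log.warning("%s: %s", rec.id, msg)
            notes.append(msg)
            continue
        meta = {
            k[len(_META_PREFIX):]: v[0]
            for k, v in sf.qualifiers.items()
            if k.startswith(_META_PREFIX)
        }
        feats.append(Feature(label, int(sf.location.start), int(sf.location.end), role, meta))
    return DuplexFragment(str(rec.seq), topology, left, right, feats,
                          name=rec.id if rec.id != "fragment" else "", notes=notes)


def write_genbank(molecule: DuplexFragment, path: str | Path) -> None:
    SeqIO.write([to_seqrecord(molecule)], str(path), "genbank")


def read_genbank(path: str | Path) -> DuplexFragment:
    try:
        rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad records
        raise ParseError(f"malformed GenBank file {path}: {exc}") from exc
    return from_seqrecord(rec)


def write_fasta(molecules: list[DuplexFragment] | DuplexFragment, path: str | Path) -> None:
    if isinstance(molecules, DuplexFragment):
        molecules = [molecules]
    SeqIO.write([to_seqrecord(m) for m in molecules], str(path), "fasta")


def read_fasta(path: str | Path) -> list[DuplexFragment]:
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise ParseError(f"malformed FASTA file {path}: {exc}") from exc
    out = []
    for rec in records:
        topology, left, right = _parse_ends(rec.description)
        out.append(DuplexFragment(str(rec.seq), topology, left, right,
                                  name=rec.id if rec.id != "fragment" else ""))
    return out
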