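"""Parsing of protein-level HGVS substitution strings.

Only single-residue missense substitutions (``p.Ala123Thr`` or ``p.A123T``)
are accepted; nonsense, frameshift, synonymous and indel notations raise
:class:`~neoprio.errors.UnsupportedVariantClass` so callers can distinguish
"not missense" from "not HGVS".
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import HgvsParseError, UnsupportedVariantClass

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

STANDARD_AA = frozenset(AA3_TO_1.values())

_RE_THREE = re.compile(r"^p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|=|\*)\)?$")
_RE_ONE = re.compile(r"^p\.\(?([A-Z])(\d+)([A-Z*=])\)?$")
_UNSUPPORTED_MARKERS = ("fs", "del", "dup", "ins", "ext", "Ter")


@dataclass(frozen=True)
class ProteinSubstitution:
    """A parsed single-residue substitution, one-letter codes, 1-based."""

    wt: str
    pos: int
    mut: str


def parse_protein_hgvs(text: str) -> ProteinSubstitution:
    """Parse ``p.<aa><pos><aa>`` (one- or three-letter codes).

    Raises
    ------
    UnsupportedVariantClass
        For nonsense (``Ter``/``*``), synonymous (``=`` or identical
        residues), frameshift and indel notations.
    HgvsParseError
        For anything that is not recognizable protein HGVS.
    """
    text = text.strip()
    if not text.startswith("p."):
        raise HgvsParseError(f"not a protein HGVS string: {text!r}")
    body = text[2:]
    if any(marker in body for marker in _UNSUPPORTED_MARKERS):
        raise UnsupportedVariantClass(f"unsupported variant class: {text!r}")

    m = _RE_THREE.match(text)
    if m:
        wt3, pos, mut3 = m.groups()
        if wt3 not in AA3_TO_1:
            raise HgvsParseError(f"unknown residue code {wt3!r} in {text!r}")
        if mut3 in ("=",):
            raise UnsupportedVariantClass(f"synonymous variant: {text!r}")
        if mut3 == "*":
            raise UnsupportedVariantClass(f"nonsense variant: {text!r}")
        if mut3 not in AA3_TO_1:
            raise HgvsParseError(f"unknown residue code {mut3!r} in {text!r}")
        wt, mut = AA3_TO_1[wt3], AA3_TO_1[mut3]
    else:
        m = _RE_ONE.match(text)
        if not m:
            raise HgvsParseError(f"unparseable protein HGVS: {text!r}")
        wt, pos, mut = m.groups()
        if mut == "*":
            raise UnsupportedVariantClass(f"nonsense variant: {text!r}")
        if mut == "=":
            raise UnsupportedVariantClass(f"synonymous variant: {text!r}")
        if wt not in STANDARD_AA or mut not in STANDARD_AA:
            raise HgvsParseError(f"non-standard residue in {text!r}")

    if wt == mut:
        raise UnsupportedVariantClass(f"synonymous variant: {text!r}")
    return ProteinSubstitution(wt=wt, pos=int(pos), mut=mut)


def is_missense(text: str) -> bool:
    """True iff *text* denotes a single-residue missense substitution."""
    try:
        parse_protein_hgvs(text)
    except (HgvsParseError, UnsupportedVariantClass):
        return False
    return True
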