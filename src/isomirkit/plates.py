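"""Sequence-derived "license plate" identifiers for short RNA molecules.

A license plate is an assembly-independent, universally unique name of the
form ``<prefix>-<length>-<payload>`` that is a bijection with the underlying
DNA sequence.  The payload packs the sequence at 2 bits per nucleotide
(A=00, C=01, G=10, T=11) and emits one symbol of a fixed 32-character
alphabet per 5 bits; a final group of fewer than 5 bits is taken at face
value.  The alphabet interleaves the digits 0-9 with the letters B-Z,
deliberately omitting the four nucleotide letters A, C, G and T so that a
payload can never be mistaken for a raw sequence.

Because the mapping depends only on the sequence itself, plates are stable
across genome assemblies and database releases, and need no central naming
authority.  The scheme is the MINTplates encoding originally introduced for
tRNA-derived fragments; with the ``iso`` prefix it names miRNA isoforms
(isomiRs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["LicensePlate", "encode", "decode", "PlateError"]

#: 32-symbol payload alphabet: B-Z minus {A,C,G,T}, digits at every third slot.
ALPHABET = "BD0EF1HI2JK3LM4NO5PQ6RS7UV8WX9YZ"

_SYMBOL_VALUE = {c: i for i, c in enumerate(ALPHABET)}
_NT_BITS = {"A": "00", "C": "01", "G": "10", "T": "11"}
_BITS_NT = {v: k for k, v in _NT_BITS.items()}

_PLATE_RE = re.compile(r"^(?P<prefix>[A-Za-z]+)-(?P<length>\d+)-(?P<payload>[A-Z0-9]+)$")


class PlateError(ValueError):
    """Raised for malformed plates or non-encodable sequences."""


@dataclass(frozen=True)
class LicensePlate:
    """A parsed license plate: ``prefix-length-payload``."""

    prefix: str
    length: int
    payload: str

    def __str__(self) -> str:
        return f"{self.prefix}-{self.length}-{self.payload}"

    @classmethod
    def parse(cls, text: str) -> "LicensePlate":
        m = _PLATE_RE.match(text.strip())
        if not m:
            raise PlateError(f"malformed license plate: {text!r}")
        return cls(m["prefix"], int(m["length"]), m["payload"])


def payload_size(seq_length: int) -> int:
    """Number of payload symbols for a sequence of ``seq_length`` nt: ceil(2L/5)."""
    return -(-2 * seq_length // 5)


def encode(seq: str, prefix: str = "iso") -> LicensePlate:
    """Encode a DNA sequence into its license plate.

    Parameters
    ----------
    seq
        Sequence over {A,C,G,T}; case-insensitive; length >= 1.
    prefix
        Molecule-class prefix (``iso`` for isomiRs).
    """
    seq = seq.upper()
    if not seq:
        raise PlateError("cannot encode an empty sequence")
    try:
        bits = "".join(_NT_BITS[c] for c in seq)
    except KeyError as exc:
        raise PlateError(f"non-ACGT character {exc.args[0]!r} in sequence") from None
    payload = "".join(ALPHABET[int(bits[i : i + 5], 2)] for i in range(0, len(bits), 5))
    return LicensePlate(prefix, len(seq), payload)


def decode(plate: LicensePlate | str) -> str:
    """Decode a license plate back into its DNA sequence.

    ``decode(encode(s)) == s`` for every valid sequence ``s``.  Raises
    :class:`PlateError` if the payload length disagrees with the length
    field, if a trailing-group symbol encodes more bits than remain, or if
    the payload contains symbols outside the plate alphabet.
    """
    if isinstance(plate, str):
        plate = LicensePlate.parse(plate)
    if plate.length < 1:
        raise PlateError("length field must be >= 1")
    expected = payload_size(plate.length)
    if len(plate.payload) != expected:
        raise PlateError(
            f"payload {plate.payload!r} has {len(plate.payload)} symbols, "
            f"expected {expected} for length {plate.length}"
        )
    nbits = 2 * plate.length
    bits = []
    for i, sym in enumerate(plate.payload):
        try:
            val = _SYMBOL_VALUE[sym]
        except KeyError:
            raise PlateError(f"symbol {sym!r} not in plate alphabet") from None
        width = min(5, nbits - 5 * i)
        if val >= (1 << width):
            raise PlateError(
                f"trailing symbol {sym!r} encodes more than the {width} remaining bits"
            )
        bits.append(format(val, f"0{width}b"))
    bitstr = "".join(bits)
    return "".join(_BITS_NT[bitstr[i : i + 2]] for i in range(0, nbits, 2))
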