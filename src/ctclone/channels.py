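"""Strand-collapsed 96-channel trinucleotide substitution conventions.

Every single-nucleotide variant is mapped to one of 96 channels defined by
the substitution in the pyrimidine frame (C>A, C>G, C>T, T>A, T>C, T>G) and
the two flanking reference bases.  Substitutions reported with a purine
reference are reverse-complemented before indexing, so the catalogue is
invariant to which strand a call was reported on.

Channel order is substitution-major: six blocks of 16 channels, each block
ordered by 5' base then 3' base alphabetically, i.e.
``A[C>A]A, A[C>A]C, ..., T[T>G]T``.  This is the conventional plotting
order for mutational-signature work.
"""

from __future__ import annotations

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

#: The 96 channel labels, in catalogue order.
CHANNELS = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_SUB_INDEX = {s: i for i, s in enumerate(SUBSTITUTIONS)}
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"invalid DNA base in {seq!r}") from exc


def pyrimidine_context(ref: str, alt: str, context3: str) -> tuple[str, str]:
    """Map an SNV to the pyrimidine frame.

    Returns ``(substitution, trinucleotide)`` where the substitution is one
    of the six pyrimidine classes and the trinucleotide is the (possibly
    reverse-complemented) reference 3-mer, whose middle base is always the
    pyrimidine reference.
    """
    for name, value in (("ref", ref), ("alt", alt)):
        if value not in _COMPLEMENT:
            raise ValueError(f"invalid {name} allele {value!r}: must be one of A/C/G/T")
    if ref == alt:
        raise ValueError(f"ref and alt alleles are identical ({ref!r}): not a substitution")
    if len(context3) != 3 or any(b not in _COMPLEMENT for b in context3):
        raise ValueError(f"invalid trinucleotide context {context3!r}")
    if context3[1] != ref:
        raise ValueError(
            f"context middle base {context3[1]!r} does not match ref allele {ref!r}"
        )
    if ref in ("A", "G"):  # purine frame: flip to the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context3 = revcomp(context3)
    return f"{ref}>{alt}", context3


def snv_channel(ref: str, alt: str, context3: str) -> int:
    """Channel index (0-95) of an SNV given its reference trinucleotide."""
    sub, ctx = pyrimidine_context(ref, alt, context3)
    return _SUB_INDEX[sub] * 16 + _BASE_INDEX[ctx[0]] * 4 + _BASE_INDEX[ctx[2]]


def channel_label(index: int) -> str:
    """Human-readable label (e.g. ``"T[C>G]A"``) for a channel index."""
    return CHANNELS[index]


def is_apobec_site(ref: str, alt: str, context3: str) -> bool:
    """True if an SNV falls at an APOBEC consensus trinucleotide.

    The consensus set is T(C>G)T, T(C>G)A and T(C>A)N, evaluated on either
    strand (purine-frame calls are reverse-complemented first).
    """
    sub, ctx = pyrimidine_context(ref, alt, context3)
    if sub == "C>G":
        return ctx in ("TCT", "TCA")
    if sub == "C>A":
        return ctx[0] == "T"
    return False


#: Channel indices of the APOBEC consensus set (pyrimidine frame).
APOBEC_CHANNELS = tuple(
    i
    for i, label in enumerate(CHANNELS)
    if is_apobec_site(label[2], label[4], label[0] + label[2] + label[6])
)
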