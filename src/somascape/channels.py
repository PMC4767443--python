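"""Trinucleotide contexts, the 96 substitution channels, and mutation categories.

Single-base substitutions are represented on the pyrimidine strand: a mutation whose
reference base is a purine (A or G) is reverse-complemented, together with its
trinucleotide context, before classification.  The 96-channel order is the conventional
COSMIC ordering: the six pyrimidine substitutions C>A, C>G, C>T, T>A, T>C, T>G, each
expanded over the 16 flanking contexts sorted lexicographically by 5' then 3' base.
"""

from __future__ import annotations

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Seven mutation categories used for background-mutation-rate estimation.  The six
#: substitution labels split C/G sites by CpG dinucleotide context; indels are their
#: own category.
CATEGORIES = (
    "AT_transition",
    "AT_transversion",
    "CpG_transition",
    "CpG_transversion",
    "CG_transition",
    "CG_transversion",
    "indel",
)

#: Site classes whose per-gene base counts determine category opportunity.
SITE_CLASSES = ("AT", "CpG", "CG")

CATEGORY_TO_CLASS = {
    "AT_transition": "AT",
    "AT_transversion": "AT",
    "CpG_transition": "CpG",
    "CpG_transversion": "CpG",
    "CG_transition": "CG",
    "CG_transversion": "CG",
    # indel opportunity is the full covered footprint, handled separately
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in {seq!r}") from exc


def is_indel(ref: str, alt: str) -> bool:
    return len(ref) != 1 or len(alt) != 1 or "-" in (ref, alt)


def normalize_pyrimidine(ref: str, alt: str, context: str) -> tuple[str, str, str, bool]:
    """Return (ref, alt, context, flipped) with the reference base a pyrimidine.

    ``context`` is the 5' base + ref + 3' base as observed on the sequenced strand;
    its middle base must equal ``ref``.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not bracket ref {ref!r}")
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if any(b not in BASES for b in context):
        raise ValueError(f"non-ACGT base in context {context!r}")
    if ref in ("A", "G"):
        return COMPLEMENT[ref], COMPLEMENT[alt], revcomp(context), True
    return ref, alt, context, False


def _channel_labels() -> tuple[str, ...]:
    labels = []
    for sub in SUBSTITUTIONS:
        ref = sub[0]
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return tuple(labels)


#: Fixed channel order; emitted in output headers so files are self-describing.
CHANNELS_96 = _channel_labels()

#: The 32 pyrimidine-centred trinucleotide contexts (16 NCN then 16 NTN,
#: lexicographic by 5' then 3' base), used for opportunity bookkeeping.
CONTEXTS_32 = tuple(
    f"{five}{mid}{three}" for mid in ("C", "T") for five in BASES for three in BASES
)

_CHANNEL_INDEX = {lab: i for i, lab in enumerate(CHANNELS_96)}
_CONTEXT_INDEX = {ctx: i for i, ctx in enumerate(CONTEXTS_32)}


def channel_label(ref: str, alt: str, context: str) -> str:
    ref, alt, context, _ = normalize_pyrimidine(ref, alt, context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def channel_index(ref: str, alt: str, context: str) -> int:
    """Index into the fixed 96-channel order, after pyrimidine normalization."""
    return _CHANNEL_INDEX[channel_label(ref, alt, context)]


def channel_parts(index: int) -> tuple[str, str, str]:
    """Inverse of :func:`channel_index`: (ref, alt, pyrimidine-strand context)."""
    lab = CHANNELS_96[index]
    return lab[2], lab[4], lab[0] + lab[2] + lab[6]


def context_index(context: str) -> int:
    """Index of a pyrimidine-centred context among the 32; purine contexts flipped."""
    context = context.upper()
    if context[1] in ("A", "G"):
        context = revcomp(context)
    return _CONTEXT_INDEX[context]


def channels_of_context(context: str) -> tuple[int, int, int]:
    """The three channel indices sharing one pyrimidine-centred context."""
    context = context.upper()
    if context[1] in ("A", "G"):
        context = revcomp(context)
    ref = context[1]
    alts = [sub[2] for sub in SUBSTITUTIONS if sub[0] == ref]
    return tuple(_CHANNEL_INDEX[f"{context[0]}[{ref}>{a}]{context[2]}"] for a in alts)


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def categorize(ref: str, alt: str, context: str | None = None) -> str:
    """Classify a mutation into one of the seven categories.

    A/T reference sites give AT_* categories; C/G sites are split by whether the
    pyrimidine-strand context carries a 3' G (a CpG dinucleotide).  Transitions are
    A<->G and C<->T.  Length-discordant alleles are indels and need no context.
    """
    if is_indel(ref, alt):
        return "indel"
    if context is None:
        raise ValueError("substitutions require a trinucleotide context")
    ref_n, alt_n, context_n, _ = normalize_pyrimidine(ref, alt, context)
    transition = (ref_n, alt_n) in _TRANSITIONS
    if ref_n == "T":  # A/T site on the pyrimidine strand
        return "AT_transition" if transition else "AT_transversion"
    if context_n[2] == "G":
        return "CpG_transition" if transition else "CpG_transversion"
    return "CG_transition" if transition else "CG_transversion"
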