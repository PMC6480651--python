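"""Fixed vocabularies: the 13 sub-nuclear compartments and the amino-acid alphabet."""

# Canonical compartment order (largest annotation classes first).
COMPARTMENTS: tuple[str, ...] = (
    "chromatin",
    "nucleolus",
    "nuclear speckle",
    "PML body",
    "nuclear lamina",
    "nuclear matrix",
    "nuclear envelope",
    "Cajal body",
    "nuclear pore complex",
    "nucleoplasm",
    "kinetochore",
    "spindle apparatus",
    "perinucleolar",
)

#: Row label used in confusion matrices for proteins with no predicted compartment.
NONE_LABEL = "None"

#: Positive label of the nucleus-vs-elsewhere classifier.
TRAVELER_LABEL = "traveler"

# PSI-BLAST column order; also the digit order for base-20 k-mer indexing.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_CANONICAL = {c.lower(): c for c in COMPARTMENTS}


def canonical_compartment(label: str) -> str:
    """Map a label to its canonical spelling, case-insensitively.

    Raises ``ValueError`` listing the valid vocabulary for unknown labels.
    """
    key = label.strip().lower()
    if key not in _CANONICAL:
        raise ValueError(
            f"unknown compartment label {label!r}; valid labels: "
            + ", ".join(COMPARTMENTS)
        )
    return _CANONICAL[key]
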