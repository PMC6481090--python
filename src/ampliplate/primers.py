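"""Standard dual-barcode primer set for 96-well amplicon screening.

Eight forward "row" primers (iR5_A..iR5_H) and twelve reverse "column"
primers (iC701..iC712) address the 96 wells of a plate in all 8 x 12
combinations.  Each primer is a 3 bp spacer (GAT), an 8 bp well barcode,
and an m13-derived universal linker that primes off the locus-specific
first-round PCR product (m13fwd for rows, m13rev for columns).

The barcodes within each group are maximally distinguishable: every pair
differs at several positions, so a single sequencing error in the barcode
window cannot move a read to a different well.
"""

from __future__ import annotations

# (id, full primer sequence = spacer + barcode + linker)
DEFAULT_ROW_PRIMERS: tuple[tuple[str, str], ...] = (
    ("iR5_A", "GATTATAGCCTGTAAAACGACGGCCAGT"),
    ("iR5_B", "GATATAGAGGCGTAAAACGACGGCCAGT"),
    ("iR5_C", "GATCCTATCCTGTAAAACGACGGCCAGT"),
    ("iR5_D", "GATGGCTCTGAGTAAAACGACGGCCAGT"),
    ("iR5_E", "GATAGGCGAAGGTAAAACGACGGCCAGT"),
    ("iR5_F", "GATTAATCTTAGTAAAACGACGGCCAGT"),
    ("iR5_G", "GATCAGGACGTGTAAAACGACGGCCAGT"),
    ("iR5_H", "GATGTACTGACGTAAAACGACGGCCAGT"),
)

DEFAULT_COLUMN_PRIMERS: tuple[tuple[str, str], ...] = (
    ("iC701", "GATATTACTCGAGCGGATAACAATTTCACACAGGA"),
    ("iC702", "GATTCCGGAGAAGCGGATAACAATTTCACACAGGA"),
    ("iC703", "GATCGCTCATTAGCGGATAACAATTTCACACAGGA"),
    ("iC704", "GATGAGATTCCAGCGGATAACAATTTCACACAGGA"),
    ("iC705", "GATATTCAGAAAGCGGATAACAATTTCACACAGGA"),
    ("iC706", "GATGAATTCGTAGCGGATAACAATTTCACACAGGA"),
    ("iC707", "GATCTGAAGCTAGCGGATAACAATTTCACACAGGA"),
    ("iC708", "GATTAATGCGCAGCGGATAACAATTTCACACAGGA"),
    ("iC709", "GATCGGCTATGAGCGGATAACAATTTCACACAGGA"),
    ("iC710", "GATTCCGCGAAAGCGGATAACAATTTCACACAGGA"),
    ("iC711", "GATTCTCGCGCAGCGGATAACAATTTCACACAGGA"),
    ("iC712", "GATAGCGATAGAGCGGATAACAATTTCACACAGGA"),
)


def default_scheme():
    """Build the standard iR5/iC7 :class:`~ampliplate.demux.BarcodeScheme`."""
    from .demux import scheme_from_primers

    return scheme_from_primers(list(DEFAULT_ROW_PRIMERS), list(DEFAULT_COLUMN_PRIMERS))
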