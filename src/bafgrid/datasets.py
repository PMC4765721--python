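"""Bundled example data.

The candidate-loci list shipped here is synthetic: hg19-style chromosome
names with plausible spacing, generated deterministically, for examples
and tests only.  Real analyses should supply a loci table derived from a
common-SNP catalogue matching their reference genome.
"""

from importlib import resources


def example_loci_path() -> str:
    """Path to the bundled synthetic candidate-loci TSV."""
    return str(resources.files("bafgrid").joinpath("data/example_loci_synthetic.tsv"))
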