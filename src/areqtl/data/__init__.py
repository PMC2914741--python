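"""Bundled fixture data.

``are_training_sites()`` returns the synthetic ARE (NRF2 binding site)
training alignment — a documented stand-in collection, not the originally
curated experimental sites; ``default_gene_sets()`` returns the bundled GMT
(a 37-symbol ARE set plus a control pathway).
"""

from importlib.resources import files


def are_sites_path():
    return files(__package__) / "are_sites.synthetic.fasta"


def gene_sets_path():
    return files(__package__) / "gene_sets.gmt"


def are_training_sites() -> list[str]:
    from ..io import read_fasta

    return list(read_fasta(str(are_sites_path())).values())


def default_gene_sets():
    from ..enrichment import read_gmt

    return read_gmt(str(gene_sets_path()))
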