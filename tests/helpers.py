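"""Shared builders for scoring/report tests."""

from evanno.refdata import GeneEvidence
from evanno.variant_io import Variant
from evanno.vep_ingest import EnrichedVariant, VepAnnotation


def make_enriched(chrom="chr1", pos=100, ref="A", alt="G", gene="GENEA",
                  zygosity="het", sift=None, polyphen=None, gmaf=None,
                  pubmed=0, cosmic=0, plen=500, diseases=(), terms=()):
    v = Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, sample_id="s",
                zygosity=zygosity)
    ann = VepAnnotation(key=v.key, gene_symbol=gene, sift=sift,
                        polyphen=polyphen, gmaf=gmaf)
    ev = GeneEvidence(gene_symbol=gene, pubmed_count=pubmed, cosmic_count=cosmic,
                      protein_length=plen, disease_names=list(diseases),
                      process_terms=list(terms))
    return EnrichedVariant(variant=v, annotation=ann, evidence=ev)
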