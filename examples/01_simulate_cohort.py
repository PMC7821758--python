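"""Generate a synthetic tumor cohort with planted ground truth.

The generator plants co-expressed gene blocks, differential expression,
a survival/stage link on one block, a hub-structured PPI edge list and
paired methylation shifts — everything the pipeline expects from a real
tumor study, but with a known answer sheet.
"""

import coexhub as cx

cfg = cx.SynthConfig(seed=1)
expr, clinical, ppi, methylation, truth = cx.generate_all(cfg)

print(f"expression: {expr.values.shape[0]} genes x "
      f"{expr.values.shape[1]} samples "
      f"({len(expr.tumor_samples)} tumor / {len(expr.normal_samples)} normal)")
print(f"clinical:   {clinical.shape[0]} tumor samples, "
      f"{int(clinical['status'].sum())} observed deaths "
      f"({1 - clinical['status'].mean():.0%} censored)")
print(f"ppi:        {len(ppi)} scored edges over the prognostic module")
print(f"methylation: {methylation.values.shape[0]} genes x "
      f"{methylation.values.shape[1]} samples "
      f"({len(methylation.pairing)} tumor/normal pairs)")
print("planted truth:")
print(f"  blocks: {truth.module_of_gene[truth.module_of_gene >= 0].value_counts().to_dict()}")
print(f"  DEGs:   {truth.deg_labels.value_counts().to_dict()}")
print(f"  prognostic block: {truth.prognostic_module}, "
      f"hubs: {truth.hub_genes}")
# The block sizes and DEG counts above are the planted answer sheet the
# later examples try to recover from the data alone.
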