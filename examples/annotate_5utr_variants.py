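"""Classify the effect of 5'UTR variants on uORF structure.

Plants one variant of each effect class on a synthetic transcriptome,
writes them as VCF, and runs extraction + annotation.  Effects follow the
uORF-structural vocabulary: gained/lost start codons, gained/lost stop
codons, frameshifts, and Kozak context changes of an existing uAUG.
"""

import tempfile

from uorfkit import annotate_effect, enumerate_candidates, extract_utr5_variants, summarize_effects
from uorfkit.synthetic_data import simulate_transcriptome, simulate_vcf

models, seqs, truth = simulate_transcriptome(
    n_tx=12, plant=(("non_overlapping", True),), seed=6
)
mix = {e: 1 for e in (
    "uAUG_gained", "uSTART_lost", "uSTOP_gained",
    "uSTOP_lost", "uFrameshift", "kozak_changed",
)}

with tempfile.NamedTemporaryFile(suffix=".vcf", mode="w", delete=False) as tmp:
    vcf_path = tmp.name
planted = simulate_vcf(models, seqs, truth, mix, out_vcf=vcf_path, seed=7)
variants, dropped = extract_utr5_variants(vcf_path, models)

effects = []
print(f"{'variant':<8}{'change':<10}{'transcript':<10}{'planted':<15}annotated")
for v in variants:
    model, seq = models[v.transcript_id], seqs[v.transcript_id]
    cands = enumerate_candidates(model, seq)
    effs = annotate_effect(v, model, seq, cands)
    effects.extend(effs)
    expected = next(r["effect"] for r in planted if r["variant_id"] == v.variant_id)
    got = ",".join(e.effect for e in effs)
    print(f"{v.variant_id:<8}{v.nucleotide_change:<10}{v.transcript_id:<10}{expected:<15}{got}")

print("\nEffect summary (counts by class and nucleotide change):")
print(summarize_effects(effects).to_string(index=False))
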