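"""Run the three Ribo-seq admission gates on good and bad libraries.

A usable library needs (i) enough reads, (ii) an RPF length distribution
within 26-34 nt peaking in 27-32 nt, and (iii) strong 3-nt periodicity:
frame 0 must hold the modal share of CDS P-sites and strictly more than
half of them.  A frame-uniform library (no periodicity) fails gate (iii).
"""

from uorfkit import build_psite_profiles, evaluate_library
from uorfkit.synthetic_data import simulate_rpf_library, simulate_transcriptome

models, seqs, truth = simulate_transcriptome(n_tx=10, seed=4)

for label, frame0_prob in (("periodic library", 0.9), ("frame-uniform library", 1 / 3)):
    hits, _, truth2 = simulate_rpf_library(
        models, seqs, truth, depth=1.0, frame0_prob=frame0_prob, seed=5
    )
    profiles = build_psite_profiles(hits, truth2.offsets, models)
    report = evaluate_library(hits, profiles, models, size_min_reads=1000)
    f0, f1, f2 = report.frame_counts
    print(f"{label}:")
    print(f"  reads={report.n_reads}  peak length={report.peak_length} nt")
    print(f"  frame counts (f0,f1,f2)=({f0},{f1},{f2})  frame0={report.frame0_fraction:.1%}")
    print(f"  gates={report.gates}  overall pass={report.passed}")
    for gate, reason in report.reasons.items():
        print(f"    {gate}: {reason}")
    print()
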