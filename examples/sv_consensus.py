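"""Consensus merging of per-sample structural-variant calls.

Simulates jittered per-sample deletion calls around a truth set (plus decoy
calls violating the size filters), applies the intake filter, merges within
samples at 80% reciprocal overlap and across samples at 50%, and prints the
resulting allele-frequency spectrum.
"""

from popvar.simulate import SimConfig, simulate_sv_calls
from popvar.sv import af_spectrum, intake_filter, merge_across_samples, merge_within_sample

cfg = SimConfig(seed=17, sv_jitter_sd=20.0)
calls, truth = simulate_sv_calls(cfg, n_samples=20, carriers_per_sv=4, n_decoys=6)

kept, dropped = intake_filter(calls)
print(f"intake: kept {len(kept)} of {len(calls)} calls, dropped {dropped}")

merged = []
for sample in sorted({c.sample for c in kept}):
    merged.extend(merge_within_sample([c for c in kept if c.sample == sample]))
consensus = merge_across_samples(merged, cohort_size=20)

print(f"consensus SVs: {len(consensus)} (truth had {len(truth['svs'])})")
for sv in sorted(consensus, key=lambda c: c.start):
    print(f"  {sv.chrom}:{sv.start}-{sv.end} {sv.sv_type} carriers={len(sv.carriers)} AF={sv.af:.2f}")
print(af_spectrum(consensus))
# Each consensus record pools one true SV's jittered per-sample calls; its
# AF is the carrier fraction, binned here into the rare/common spectrum.
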