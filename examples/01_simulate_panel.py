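"""Simulate a haploid segregant panel and inspect its genetic structure.

Builds a desk-scale two-parent cross (16 chromosomes, 1,000 markers, 500
segregants), checks Mendelian segregation and the Haldane decay of linkage,
and generates a correlated trait panel with recorded ground truth.
"""

import numpy as np

import segvar as sv

mm, geno = sv.simulate_segregant_panel(sv.PanelConfig(), n_segregants=500,
                                       seed=1)
print(f"panel: {geno.n_segregants} segregants x {geno.n_markers} markers")
print(f"mean parent-B allele frequency: {geno.allele_freq().mean():.3f} "
      "(expected 0.5: Mendelian segregation of a haploid cross)")

# adjacent-marker recombination: short map distances -> tight linkage
r = mm.interval_recomb_fractions()
same = np.diff(mm.chromosome) == 0
obs = np.mean(geno.codes[:, :-1][:, same] != geno.codes[:, 1:][:, same])
print(f"adjacent-marker recombinant fraction: observed {obs:.4f}, "
      f"Haldane expectation {r[same].mean():.4f}")

archs, panel, growth, extras = sv.simulate_traits(
    geno, sv.ArchitectureConfig(), n_replicates=2, seed=2)
h2 = [a.h2_rep_mean for a in archs]
print(f"\n{len(archs)} traits, true h2 range {min(h2):.3f}-{max(h2):.3f} "
      "(architectures scale with the importance weight w)")
print("conservation check max |V_P - (V_A+V_NonA+V_E)|:",
      max(abs(a.V_P - (a.V_A + a.V_NonA + a.V_E)) for a in archs))
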