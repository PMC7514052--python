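"""Mature-mRNA half-life from the steady-state 5'/3' abundance ratio.

At steady state, 5'/3' = (T_transcript + T_lifetime) / T_lifetime: the 5'
probe sees nascent + mature transcripts, the 3' probe essentially mature
only. With a 16 h transcription time for the 2.3 Mbp gene, the 1,550 kbp
between the probe regions takes ~11 h to traverse.
"""

from fociq import (GeneModel, ISH_SEPARATION_BP, KineticEstimate,
                   generate_steady_state_counts, transcription_time_between)

gene = GeneModel()
t_inter = transcription_time_between(gene, ISH_SEPARATION_BP)
print(f"elongation rate: {gene.elongation_rate_bp_per_s:.1f} bases/s; "
      f"inter-probe transcription time: {t_inter:.1f} h")

# the historical abundances: ~2500 (5') and ~780 (3') transcripts per ng
est = KineticEstimate.from_abundances(2500, 780, t_inter)
print(f"5'/3' ratio {est.ratio_5p_3p:.2f} -> mean lifetime "
      f"{est.mean_lifetime_h:.1f} h, half-life {est.half_life_h:.1f} h, "
      f"nascent fraction {est.nascent_fraction:.0%}")

# round trip through the synthetic steady-state generator
table = generate_steady_state_counts(gene, lifetime_h=5.0,
                                     initiation_interval_min=22,
                                     n_nuclei=80, noise_cv=0.1, seed=4,
                                     n_replicates=9, sampled=True)
by_region = table.groupby("region").counts.mean()
recovered = KineticEstimate.from_abundances(by_region["5p"], by_region["3p"],
                                            t_inter)
print(f"synthetic cohort generated at lifetime 5.0 h -> recovered "
      f"{recovered.mean_lifetime_h:.2f} h from 9 noisy replicates")
print("A transcript that takes 16 h to make persists only ~3-5 h once "
      "exported: supply exceeds demand at the mRNA level.")
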