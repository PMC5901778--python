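"""Sweep founder density for adhesive vs non-adhesive strains under strong
flow, and print the adhesion payoff delta_xi = mean xi(sigma=1) - mean
xi(sigma=0).

Under strong flow (f=1), adhesive strains profit from low founder density
(delta_xi > 0: each surviving founder claims a large territory), while at
high density the payoff shrinks. Replica counts are desk-scale; increase
n_reps for smoother curves.
"""

from biofilmca import SweepSpec, sweep

spec = SweepSpec(
    f_values=(1.0,),
    rho0_values=(1e-3, 1e-2, 1e-1),
    sigma_values=(0.0, 1.0),
    n_reps=100,
    L=60,
    base_seed=0,
)
result = sweep(spec)
print(result.summaries[["f", "rho0", "sigma", "n", "mean_xi", "std_xi"]].to_string(index=False))
print()
print("adhesion payoff (sigma=1 minus sigma=0):")
print(result.delta.to_string(index=False))
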