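"""Score ensemble members on withheld years and turn biases into weights.

Withholds the last 13 years, fits every member of the default 21-member
ensemble on the remainder, and prints the members with the largest and
smallest exp(-|bias|) weights.
"""
import mortens as mt

surface, _ = mt.generate_surface(mt.SurfaceParams(seed=5))
val = mt.run_validate([surface], mt.default_ensemble(), holdout=13,
                      draws_per_model=300, seed=0)

wt = val.weight_tables[(surface.country, surface.sex)]
df = wt.to_frame().sort_values("weight", ascending=False)
print(df.head(3).to_string(index=False))
print("...")
print(df.tail(3).to_string(index=False))
print(f"weights sum to {wt.weights.sum():.12f}; a member that mis-projects "
      "life expectancy by 1 year receives e^-1 = 0.37x the weight of an "
      "unbiased member.")
unit = (surface.country, surface.sex)
print(f"pooled-ensemble bias on withheld years: {val.bma_bias[unit]:+.3f} y; "
      f"90% interval coverage: {val.bma_coverage[unit]:.2f}")
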