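"""Which estimator should you trust with five induction times?

Draws many synthetic series of each size M from a known truth and reports
the mean absolute error of each estimator.  At the published study's
conditions, error falls steadily with more observations, and for sparse
series (M <= 20) the closed-form MLE beats the least-squares direct fit for
both parameters.  (The full-scale benchmark uses 1000 datasets per M; 200
keeps this example quick.)
"""

from nucleokin import estimator_benchmark
from nucleokin.synthetic_data import benchmark_frame

results = estimator_benchmark(n_datasets=200, methods=("direct", "mle"), seed=0)
df = benchmark_frame(results)
print(df.pivot(index="M", columns="method",
               values=["mae_J", "mae_tg"]).to_string(float_format="%.4g"))
print("\nmae_J in #/(m^3 s) against the true 0.1; mae_tg in s against the "
      "true 10,000 s.\nThese MAE curves double as experimental error bands "
      "for the correlation models.")
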