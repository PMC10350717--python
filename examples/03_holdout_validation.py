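"""Hold out the 2017 wave and check whether the projection recovers it.

The final observed wave is removed; a pseudo-sample with that wave's own
size and age/sex margins is appended to the 1997-2012 data; the engine
projects 2017 and the result is compared with what the held-out wave
actually showed.  `included = True` means the observed prevalence falls
inside the projected 95% interval — the expected outcome when the trend
is stable, and the thing that *fails* when a wave breaks the trend.
"""

import numpy as np

from prevcast import EngineConfig, default_models, holdout_validation
from prevcast.synthetic import linear_trend_config, generate_survey

cfg = linear_trend_config(n_per_wave=1000)
table, truth = generate_survey(cfg, np.random.default_rng(3))

config = EngineConfig(models=default_models(table), m=10, iterations=5, seed=3)
report = holdout_validation(table, 2017, config)
print(report.round(3).to_string(index=False))
print()
true_2017 = truth[truth["year"] == 2017].set_index("sex")["prevalence"]
print(f"generating truth in 2017: male {true_2017['male']:.3f}, "
      f"female {true_2017['female']:.3f}")
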