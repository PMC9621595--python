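"""Predict the hypoglycemic regime's day-13 GTT with dose uncertainty.

Cultures fed 2.8 mM glucose for 13 days receive an 11 mM glucose load on
day 13.  The glucose dose actually delivered at an exchange is uncertain;
propagating a +/- 0.85 mM dose range through the model yields a prediction
band rather than a single curve.  The printed band brackets the pooled
glucose and insulin responses at the GTT sampling times.
"""

from isletchip import (ChipConfig, ModelParameters,
                       predict_with_dose_uncertainty, standard_protocol)

params = ModelParameters()
config = ChipConfig()
protocol = standard_protocol("hypo", gtt_days=(13,), config=config)
band = predict_with_dose_uncertainty(params, None, config, protocol,
                                     dose_halfwidth=0.85, n_grid=5,
                                     method="fixed")

print("day-13 GTT prediction band (pooled concentrations)")
print(band.measurement_table.to_string(index=False,
                                       float_format=lambda v: f"{v:.2f}"))
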