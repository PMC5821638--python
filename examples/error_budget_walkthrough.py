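"""Field-error budget of a 1-ha inventory plot with four 0.04-ha subplots.

Derives the sampling-error component from sampling-intensity arithmetic and
composes it with measurement and allometric errors into the total relative
error of field-estimated biomass.
"""

from agbmc import compose_error, required_subplots, sampling_error, sampling_intensity

intensity = sampling_intensity(n_plots=160, subplot_area=0.04, reference_area=50.0)
required = required_subplots(intensity, pixel_area=1.0, subplot_area=0.04)
samp = sampling_error(base_uncertainty=10.0, required=required, sampled=4)
total = compose_error([10.0, 11.0, samp])

print(f"sampling intensity for +/-10% on 50 ha : {intensity:.1f} %")
print(f"subplots needed per 1-ha pixel         : {required:.1f}")
print(f"sampling error with 4 subplots         : {samp:.1f} %")
print(f"total field error (RSS with 10%, 11%)  : {total:.1f} %")
# The total (~17%) is the relative error injected into every Monte-Carlo
# realization of plot biomass downstream.
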