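"""Published reference estimates for the BfR2024 dermal-absorption dataset.

Posterior-mean parameter estimates reported for the Bayesian logit-scale
mixed model fitted to the BfR2024 dataset (6340 replicates, 356 studies,
155 substances). They serve two purposes: deterministic plug-in
reconstruction of the published category predictions and prediction-
interval limits (via :meth:`~dermabs.model.ModelParams.pseudo_draw`), and
realistic default truth values for the synthetic-data generator.

The residual variance was not reported alongside these estimates; the value
here is a generator default on the same order as the variance components,
not a published number.
"""

from __future__ import annotations

from .model import ModelParams

__all__ = ["BFR2024_POSTERIOR_MEANS"]

BFR2024_POSTERIOR_MEANS = ModelParams(
    alpha=-2.34,
    beta_concentrate=-2.37,
    beta_other=-0.24,
    beta_solid=-0.94,
    beta_water_based=-0.67,
    var_substance_dilution=0.64,
    var_substance_concentrate=0.52,
    rho_substance=0.20,
    var_study=0.67,
    var_within=0.59,
    var_resid=1.0,  # not a published estimate; see module docstring
)
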