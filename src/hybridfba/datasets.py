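"""Bundled reference data."""

from importlib import resources

import pandas as pd


def load_reference_exchange_stats() -> pd.DataFrame:
    """Published summary statistics of CHO-K1 exponential-phase exchange
    fluxes: per-species mean, sample SD and CV(%) aggregated over 21
    independent fed-batch cultivations.

    Units are mmol·gDW⁻¹·h⁻¹ (the growth rate ``mu`` in h⁻¹); uptake is
    negative.  These summaries serve as the ``r_mean``/``sigma`` inputs of
    the measured-exchange-bound constraints when no raw dataset is at hand.
    """
    with resources.files("hybridfba.data").joinpath(
            "cho_k1_exchange_stats.csv").open() as fh:
        return pd.read_csv(fh, index_col="species")
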