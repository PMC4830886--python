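"""Published summary data for six candidate antifungal triazoles.

These are the printed per-compound summaries from a published screening
study of six tebuconazole-class triazole candidates (coded 0594-0618)
evaluated in the embryonic stem cell differentiation assay and the BeWo
b30 placental-barrier transport model, with antipyrine as the freely
transported reference marker and amoxicillin as a barrier-integrity
control.  The underlying well-level counts and chromatograms were not
deposited, so these tables are consumed as inputs: the transport table
feeds relative-Papp computation, the potency table feeds the corrected
ranking, and the in vivo ranking (expert-derived from a rat prenatal
developmental toxicity screen) is the external comparator.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_placental_transport",
    "load_differentiation_potency",
    "in_vivo_ranking",
    "REFERENCE_COMPOUND",
]

REFERENCE_COMPOUND = "antipyrine"

# compound, intracellular accumulation (% of added), Papp mean and SD
# (1e-6 cm/s, n=3 inserts), printed relative Papp
_TRANSPORT_ROWS = [
    ("amoxicillin", 0.0, 6.5, 0.2, 0.16),
    ("0594", 24.0, 11.5, 2.6, 0.30),
    ("0595", 79.0, 3.0, 0.4, 0.08),
    ("0596", 12.0, 24.4, 2.7, 0.63),
    ("0599", 22.0, 18.4, 1.1, 0.47),
    ("0600", 66.0, 7.9, 1.0, 0.20),
    ("0618", 56.0, 7.1, 0.2, 0.18),
    ("antipyrine", 0.0, 38.9, 3.0, 1.00),
]

# compound, BMC_d50 (uM), printed transfer-corrected BMC_d50 (uM)
_POTENCY_ROWS = [
    ("0594", 6.9, 23.3),
    ("0595", 11.0, 141.8),
    ("0596", 11.4, 18.1),
    ("0599", 1.8, 3.8),
    ("0600", 4.2, 21.0),
    ("0618", 4.3, 23.7),
]

# expert-derived in vivo potency ordering, least toxic -> most toxic
_IN_VIVO_LEAST_TO_MOST = ["0595", "0618", "0594", "0600", "0596", "0599"]


def load_placental_transport() -> pd.DataFrame:
    """Transport summary: accumulation, Papp (mean, SD) and the printed
    relative Papp, indexed by compound."""
    return pd.DataFrame(
        _TRANSPORT_ROWS,
        columns=[
            "compound",
            "accumulation_percent",
            "papp_1e6_cm_s_mean",
            "papp_1e6_cm_s_sd",
            "relative_papp_printed",
        ],
    ).set_index("compound")


def load_differentiation_potency() -> pd.DataFrame:
    """Differentiation potency summary: BMC_d50 and the printed corrected
    BMC_d50, indexed by compound.

    The printed corrected values were derived from unrounded
    intermediates; recomputing them from the printed (rounded) BMC and
    relative Papp reproduces 18.1/3.8/21.0 exactly but differs in the
    last digit for 0594, 0595 and 0618.
    """
    return pd.DataFrame(
        _POTENCY_ROWS,
        columns=["compound", "bmc_d50_um", "corrected_bmc_d50_um_printed"],
    ).set_index("compound")


def in_vivo_ranking(most_potent_first: bool = True) -> list[str]:
    """The external in vivo developmental-toxicity potency ordering."""
    order = list(_IN_VIVO_LEAST_TO_MOST)
    return order[::-1] if most_potent_first else order
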