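"""Reference parameter sets for GR/MR nuclear mobility conditions.

Published single-molecule (SMM) and FRAP estimates for the glucocorticoid
and mineralocorticoid receptors under a panel of ligands and for three GR
deletion mutants.  These serve as ground truth for synthetic experiments:
the SMM side fixes the diffusing-fraction size and both diffusion
coefficients, the FRAP side fixes the three-population split and the two
residence times.  Percentages are of the nuclear population; times in
seconds; D in µm²/s; ± values are SEMs (3 cell groups for SMM, top-10 fits
for FRAP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .kinetics import MotionModel


@dataclass(frozen=True)
class ConditionParameters:
    """One receptor/ligand condition with its SMM and FRAP estimates."""

    key: str
    receptor: str
    ligand: str
    smm_diffusing_pct: float
    smm_diffusing_sem: float
    d_fast: float
    d_fast_sem: float
    d_slow: float
    d_slow_sem: float
    frap_diffusing_pct: float
    frap_diffusing_sem: float
    frap_short_pct: float
    frap_short_sem: float
    tau_short: float
    tau_short_sem: float
    frap_long_pct: float
    frap_long_sem: float
    tau_long: float
    tau_long_sem: float
    synthetic: bool = False  # True where values are constructed, not measured

    def smm_ground_truth(self) -> MotionModel:
        """Generating model for single-molecule simulations.

        The diffusing fraction and both diffusion coefficients come from
        the SMM estimates; the bound population is split between the short
        and long states in the FRAP proportions (SMM itself resolves only
        the combined bound fraction at millisecond lags).
        """
        free = self.smm_diffusing_pct / 100.0
        bound = 1.0 - free
        tot = self.frap_short_pct + self.frap_long_pct
        w_short = self.frap_short_pct / tot if tot > 0 else 0.0
        return MotionModel(
            fraction_free=free,
            fraction_short=bound * w_short,
            fraction_long=bound * (1.0 - w_short),
            d_free=self.d_fast,
            d_bound=min(self.d_slow, self.d_fast),
            tau_short=self.tau_short,
            tau_long=self.tau_long,
        )

    def frap_ground_truth(self) -> MotionModel:
        """Generating model for FRAP simulations (bound states immobile)."""
        return MotionModel(
            fraction_free=self.frap_diffusing_pct / 100.0,
            fraction_short=self.frap_short_pct / 100.0,
            fraction_long=self.frap_long_pct / 100.0,
            d_free=self.d_fast,
            d_bound=0.0,
            tau_short=self.tau_short,
            tau_long=self.tau_long,
        )


def _c(key, receptor, ligand, smm, dfast, dslow, frap_diff, frap_short, ts,
       frap_long, tl, synthetic=False) -> ConditionParameters:
    return ConditionParameters(
        key,
        receptor,
        ligand,
        *smm,
        *dfast,
        *dslow,
        *frap_diff,
        *frap_short,
        *ts,
        *frap_long,
        *tl,
        synthetic=synthetic,
    )


CONDITIONS: dict[str, ConditionParameters] = {
    c.key: c
    for c in [
        _c("gr_dflu", "GR wt", "d-fludrocortisone", (46.3, 2.6), (1.38, 0.11),
           (0.05, 0.004), (43, 2.6), (33, 2.1), (0.8, 0.1), (24, 2.2), (2.9, 0.5)),
        _c("gr_dex", "GR wt", "dexamethasone", (55.1, 2.0), (1.31, 0.13),
           (0.03, 0.009), (44, 2.2), (33, 2.6), (0.7, 0.1), (23, 2.6), (2.3, 0.3)),
        _c("gr_predn", "GR wt", "prednisolone", (60.7, 3.1), (2.20, 0.11),
           (0.09, 0.008), (42, 2.5), (36, 1.6), (0.7, 0.1), (22, 2.5), (4.0, 0.8)),
        _c("gr_csol", "GR wt", "cortisol", (55.6, 3.5), (1.77, 0.10),
           (0.04, 0.003), (58, 2.0), (19, 3.8), (0.5, 0.1), (23, 2.6), (2.0, 0.0)),
        _c("gr_cort", "GR wt", "corticosterone", (74.1, 3.3), (2.49, 0.24),
           (0.08, 0.024), (66, 2.2), (26, 3.7), (0.6, 0.1), (8, 2.5), (1.2, 0.3)),
        _c("gr_ru486", "GR wt", "RU486", (69.1, 2.4), (2.86, 0.11),
           (0.14, 0.018), (66, 1.6), (24, 3.1), (0.5, 0.1), (10, 2.6), (1.4, 0.3)),
        _c("mr_aldo", "MR wt", "aldosterone", (54.1, 3.4), (1.43, 0.04),
           (0.05, 0.002), (45, 1.7), (32, 2.0), (0.8, 0.1), (23, 2.1), (2.9, 0.5)),
        _c("mr_cort", "MR wt", "corticosterone", (50.7, 1.4), (1.37, 0.13),
           (0.08, 0.005), (47, 2.1), (31, 2.3), (0.7, 0.1), (22, 2.5), (3.4, 0.8)),
        _c("mr_csol", "MR wt", "cortisol", (51.5, 0.8), (1.96, 0.19),
           (0.05, 0.002), (44, 2.2), (32, 2.9), (0.6, 0.1), (24, 2.7), (2.3, 0.3)),
        _c("mr_doc", "MR wt", "deoxycorticosterone", (60.5, 3.6), (1.60, 0.13),
           (0.06, 0.003), (57, 1.5), (23, 3.0), (0.6, 0.1), (20, 3.1), (2.3, 0.3)),
        _c("mr_dex", "MR wt", "dexamethasone", (64.3, 6.0), (1.74, 0.20),
           (0.04, 0.003), (67, 2.1), (22, 4.4), (0.7, 0.1), (11, 3.1), (1.7, 0.5)),
        _c("mr_spiro", "MR wt", "spironolactone", (78.8, 2.3), (2.71, 0.05),
           (0.06, 0.018), (71, 3.5), (23, 3.7), (0.5, 0.1), (6, 1.6), (1.2, 0.3)),
        _c("mr_epler", "MR wt", "eplerenone", (68.2, 6.6), (2.49, 0.12),
           (0.06, 0.004), (66, 1.6), (25, 2.7), (0.6, 0.1), (9, 2.3), (1.7, 0.5)),
        _c("gr_daf1_dex", "GR dAF-1", "dexamethasone", (46.5, 1.9), (0.61, 0.08),
           (0.00, 0.006), (57, 3.0), (18, 3.6), (0.6, 0.1), (25, 3.4), (2.1, 0.4)),
        _c("gr_daf1_cort", "GR dAF-1", "corticosterone", (64.7, 2.8), (2.69, 0.08),
           (0.05, 0.012), (62, 2.5), (27, 4.0), (0.6, 0.1), (11, 2.3), (1.6, 0.3)),
        _c("gr_ddbd_dex", "GR dDBD", "dexamethasone", (75.6, 3.4), (2.27, 0.15),
           (0.01, 0.006), (66, 1.6), (25, 2.7), (0.5, 0.1), (9, 2.3), (1.4, 0.3)),
        _c("gr_ddbd_cort", "GR dDBD", "corticosterone", (81.3, 1.0), (2.37, 0.19),
           (0.06, 0.004), (79, 3.1), (18, 3.9), (0.5, 0.1), (3, 1.5), (0.6, 0.3)),
        _c("gr_dlbd_dex", "GR dLBD", "dexamethasone", (86.5, 1.9), (2.71, 0.08),
           (0.03, 0.010), (82, 3.3), (16, 3.1), (0.4, 0.1), (2, 1.3), (0.4, 0.3)),
        # Controls.  The vehicle (no-hormone) row only reports the combined
        # immobile fraction (16.6 ± 5.0 %); the split, residence times and
        # diffusion coefficients here are synthetic stand-ins chosen from
        # the inactive-receptor end of the measured ranges.
        _c("gr_vehicle", "GR wt", "vehicle", (83.4, 5.0), (2.9, 0.2),
           (0.06, 0.01), (83.4, 5.0), (12.6, 3.0), (0.5, 0.1), (4.0, 2.0),
           (1.2, 0.3), synthetic=True),
        # Fixed-cell control: everything permanently immobilized.
        _c("fixed_cell", "GR wt", "dexamethasone (fixed)", (0.0, 0.0),
           (1.31, 0.0), (0.0, 0.0), (0.0, 0.0), (0.0, 0.0), (0.5, 0.0),
           (100.0, 0.0), (math.inf, 0.0), synthetic=True),
    ]
}


def get_condition(key: str) -> ConditionParameters:
    try:
        return CONDITIONS[key]
    except KeyError:
        raise KeyError(
            f"unknown condition {key!r}; available: {sorted(CONDITIONS)}"
        ) from None
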