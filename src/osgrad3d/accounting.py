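"""Image-derived carbon-fraction bookkeeping per aggregate.

For each material class the Os "amount" is the product of its mean Os_CT
and its volume fraction of the non-exterior volume, so the class amounts
sum exactly to the whole-aggregate mean Os. The matrix amount serves as the
image-derived proxy for mineral-associated organic matter (a proxy only —
mineral Os sorption precludes equating matrix Os with MAOM content), and
the share of carbon in fibrous POM is the ratio of the fibrous Os amount to
the total POM object Os amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .morphology import POM_COMPACT, POM_FIBROUS
from .volumes import EXTERIOR, LabelVolume, ScalarVolume


@dataclass
class AggregateSummary:
    aggregate_id: str
    volume_fractions: dict[str, float]
    mean_os: dict[str, float]
    os_amounts: dict[str, float]
    matrix_os_amount: float
    pom_os_amount: float
    fibrous_share: float | None  # None when no classified POM objects exist
    visible_porosity: float
    mean_matrix_gray_pre: float
    whole_aggregate_mean_os: float

    def to_row(self) -> dict:
        row = {"aggregate_id": self.aggregate_id}
        for cls, f in self.volume_fractions.items():
            row[f"frac_{cls}"] = f
        for cls, m in self.mean_os.items():
            row[f"mean_os_{cls}"] = m
        for cls, a in self.os_amounts.items():
            row[f"os_amount_{cls}"] = a
        row.update(
            matrix_os_amount=self.matrix_os_amount,
            pom_os_amount=self.pom_os_amount,
            fibrous_share=np.nan if self.fibrous_share is None else self.fibrous_share,
            visible_porosity=self.visible_porosity,
            mean_matrix_gray_pre=self.mean_matrix_gray_pre,
            whole_aggregate_mean_os=self.whole_aggregate_mean_os,
        )
        return row


def summarize_aggregate(
    labels: LabelVolume,
    os_vol: ScalarVolume,
    pre_norm: ScalarVolume,
    pom_class_volume: np.ndarray | None = None,
    aggregate_id: str = "aggregate",
) -> AggregateSummary:
    """Class-wise Os accounting for one aggregate.

    ``pom_class_volume`` codes classified POM objects (1 = fibrous,
    2 = compact, 0 = unclassified/sub-threshold); the fibrous share uses
    classified objects only and is reported as missing (None) when there are
    none — never silently as 0.
    """
    interior = labels.data != EXTERIOR
    if not interior.any():
        raise ValueError("no non-exterior voxels")
    fractions = labels.volume_fractions()
    os_data = os_vol.data
    mean_os: dict[str, float] = {}
    amounts: dict[str, float] = {}
    for cls in fractions:
        m = labels.mask(cls)
        mean_os[cls] = float(np.nanmean(os_data[m])) if m.any() else 0.0
        amounts[cls] = mean_os[cls] * fractions[cls]

    fibrous_share: float | None = None
    if pom_class_volume is not None:
        fib = pom_class_volume == POM_FIBROUS
        com = pom_class_volume == POM_COMPACT
        n_int = interior.sum()
        fib_amount = (float(np.nanmean(os_data[fib])) * fib.sum() / n_int) if fib.any() else 0.0
        com_amount = (float(np.nanmean(os_data[com])) * com.sum() / n_int) if com.any() else 0.0
        if fib_amount + com_amount > 0:
            fibrous_share = fib_amount / (fib_amount + com_amount)

    matrix_mask = labels.mask("matrix")
    return AggregateSummary(
        aggregate_id=aggregate_id,
        volume_fractions=fractions,
        mean_os=mean_os,
        os_amounts=amounts,
        matrix_os_amount=amounts.get("matrix", 0.0),
        pom_os_amount=amounts.get("POM", 0.0),
        fibrous_share=fibrous_share,
        visible_porosity=fractions.get("pore", 0.0),
        mean_matrix_gray_pre=float(np.nanmean(pre_norm.data[matrix_mask])) if matrix_mask.any() else np.nan,
        whole_aggregate_mean_os=float(np.nanmean(os_data[interior])),
    )


def cohort_table(
    summaries: list[AggregateSummary],
    regressions: list[tuple[str, str]] | None = None,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One row per aggregate, plus optional least-squares fits.

    ``regressions`` lists (x_column, y_column) pairs fitted by ordinary
    least squares with Pearson R. External covariates (e.g. laboratory TOC
    or fractionation values) may be joined on ``aggregate_id``; the tool
    never fabricates them. A regression needs at least 3 rows and a
    non-constant x; failures are reported per pair, the table is still
    returned.
    """
    table = pd.DataFrame([s.to_row() for s in summaries])
    if covariates is not None:
        table = table.merge(covariates, on="aggregate_id", how="left")
    fits = []
    for x_col, y_col in regressions or []:
        sub = table[[x_col, y_col]].dropna()
        if len(sub) < 3:
            fits.append({"x": x_col, "y": y_col, "error": "fewer than 3 rows"})
            continue
        x = sub[x_col].to_numpy(float)
        if np.ptp(x) == 0:
            fits.append({"x": x_col, "y": y_col, "error": "constant x column"})
            continue
        res = stats.linregress(x, sub[y_col].to_numpy(float))
        fits.append(
            {
                "x": x_col,
                "y": y_col,
                "slope": res.slope,
                "intercept": res.intercept,
                "r": res.rvalue,
                "error": "",
            }
        )
    return table, pd.DataFrame(fits)
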