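"""Age-stamped proxy series: the universal currency between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ProxyRecord:
    """A time series of proxy values on a declared scale.

    Parameters
    ----------
    ages : array-like
        Ages in ka before present, strictly increasing.
    values : array-like
        Proxy values (units depend on ``label``); must be finite.
    sigma : array-like, optional
        1-sigma uncertainties, same length as ``values``.
    label : str
        What the series is (e.g. ``"dD_precip_permil"``).
    """

    ages: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.ndim != 1 or self.ages.shape != self.values.shape:
            raise ValueError("ages and values must be 1-D arrays of equal length")
        if len(self.ages) > 1 and not np.all(np.diff(self.ages) > 0):
            raise ValueError("ages must be strictly increasing (no duplicates)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.values.shape:
                raise ValueError("sigma must match values in length")

    def __len__(self) -> int:
        return len(self.ages)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.ages[0]), float(self.ages[-1])

    def to_frame(self) -> pd.DataFrame:
        data = {"age_ka": self.ages, "value": self.values}
        if self.sigma is not None:
            data["sigma"] = self.sigma
        df = pd.DataFrame(data)
        df.attrs["label"] = self.label
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, value_col: str = "value", age_col: str = "age_ka",
                 sigma_col: str | None = None, label: str = "") -> "ProxyRecord":
        df = pd.read_csv(path)
        sigma = df[sigma_col].to_numpy() if sigma_col and sigma_col in df else None
        return cls(df[age_col].to_numpy(), df[value_col].to_numpy(),
                   sigma=sigma, label=label or value_col)


# ForcingSeries is structurally identical to a ProxyRecord (W/m2 or
# dimensionless after 0-1 normalization); kept as an alias for readability.
ForcingSeries = ProxyRecord
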