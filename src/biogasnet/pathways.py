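"""Methanogenic pathway classification from KO-level protein abundances.

Anaerobic digesters produce methane either from acetate (acetoclastic
methanogenesis, e.g. *Methanosarcina*) or from H2 + CO2 (hydrogenotrophic
methanogenesis, e.g. *Methanoculleus*).  The dominant route of a digester can
be read off its metaproteome: sum the relative abundances of proteins mapping
to KO terms *unique* to each pathway and form the ratio

    F = (sum of acetoclastic-unique KO abundance)
        / (sum of hydrogenotrophic-unique KO abundance).

``F >= 2.5`` calls the sample acetoclastic, ``F <= 0.4`` hydrogenotrophic, and
anything in between means both pathways contribute substantially ("both").
KO terms shared by the two pathways (the mtr complex), terms common to all
methanogenesis routes (mcr, hdr, fdh, mvh) and the methylotrophic mta terms
are excluded from F by construction but are reported alongside it.

The module ships a reference KO-abundance table for 16 full-scale agricultural
biogas plants (from a published metaproteome survey) used as a worked example
and regression fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .abundance import plant_means

#: Default classification thresholds on F.
F_LOW = 0.4
F_HIGH = 2.5

LABEL_ACETO = "acetoclastic"
LABEL_HYDRO = "hydrogenotrophic"
LABEL_BOTH = "both"


@dataclass(frozen=True)
class KoPathwaySets:
    """KO identifier sets defining the methanogenesis pathway groups.

    ``acetoclastic_unique`` (KEGG module M00357: ackA, pta, ACSS, cdh) and
    ``hydrogenotrophic_unique`` (M00567: fmd, ftr, mch, mtd, hmd, mer) enter
    factor F; ``shared_aceto_hydro`` (mtr complex), ``common`` (mcr, hdr,
    mvh, fdh) and ``methylotrophic`` (M00356: mtaABC) are reported only.
    """

    acetoclastic_unique: frozenset = frozenset(
        {"K00925", "K00625", "K01895", "K00193", "K00197", "K00194"}
    )
    hydrogenotrophic_unique: frozenset = frozenset(
        {"K00200", "K00201", "K00202", "K00203", "K11261", "K00205",
         "K00672", "K01499", "K00319", "K13942", "K00320"}
    )
    shared_aceto_hydro: frozenset = frozenset(
        {"K00577", "K00578", "K00579", "K00580", "K00581", "K00582",
         "K00583", "K00584"}
    )
    common: frozenset = frozenset(
        {"K00399", "K00401", "K00402", "K03388", "K03389", "K03390",
         "K08264", "K08265", "K14126", "K14127", "K22516", "K00125"}
    )
    methylotrophic: frozenset = frozenset({"K14080", "K04480", "K14081"})

    GROUPS = ("acetoclastic_unique", "hydrogenotrophic_unique",
              "shared_aceto_hydro", "common", "methylotrophic")

    def __post_init__(self):
        sets = [getattr(self, g) for g in self.GROUPS]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(
                        f"KO sets {self.GROUPS[i]} and {self.GROUPS[j]} overlap: "
                        f"{sorted(overlap)}"
                    )
        if not self.acetoclastic_unique or not self.hydrogenotrophic_unique:
            raise ValueError("pathway-unique KO sets must be nonempty")


_FILE_GROUP_TO_FIELD = {
    "acetoclastic": "acetoclastic_unique",
    "hydrogenotrophic": "hydrogenotrophic_unique",
    "shared": "shared_aceto_hydro",
    "common": "common",
    "methylotrophic": "methylotrophic",
}


def load_pathway_ko_sets(override_path=None) -> KoPathwaySets:
    """Return the packaged KO pathway sets, or load an override TSV.

    The override file has columns ``ko`` and ``pathway_group`` with group
    values acetoclastic / hydrogenotrophic / shared / common / methylotrophic.
    Overlapping groups raise ``ValueError``.
    """
    if override_path is None:
        return KoPathwaySets()
    table = pd.read_csv(override_path, sep="\t", dtype=str)
    for col in ("ko", "pathway_group"):
        if col not in table.columns:
            raise ValueError(f"KO set override {override_path} missing column {col!r}")
    groups: dict[str, set] = {f: set() for f in _FILE_GROUP_TO_FIELD.values()}
    for ko, grp in zip(table["ko"], table["pathway_group"]):
        if grp not in _FILE_GROUP_TO_FIELD:
            raise ValueError(f"unknown pathway_group {grp!r} in {override_path}")
        groups[_FILE_GROUP_TO_FIELD[grp]].add(ko)
    return KoPathwaySets(**{k: frozenset(v) for k, v in groups.items()})


def load_reference_ko_table():
    """Packaged 16-plant reference: (KO x plant abundance table, group labels).

    Returns a tuple ``(table, groups)`` where ``table`` is a DataFrame of mean
    relative abundances (percent of total protein abundance) indexed by KO with
    one column per plant BP01..BP16, and ``groups`` is a Series mapping each KO
    to its pathway group.
    """
    path = resources.files("biogasnet.data") / "methanogenesis_ko_reference.tsv"
    with resources.as_file(path) as fp:
        raw = pd.read_csv(fp, sep="\t", index_col="ko")
    groups = raw.pop("pathway_group")
    return raw.astype(float), groups


#: Dominant-pathway calls for the 16 reference plants as published.
REFERENCE_PLANT_LABELS = {
    "BP01": LABEL_ACETO, "BP02": LABEL_ACETO, "BP03": LABEL_ACETO,
    "BP04": LABEL_HYDRO, "BP05": LABEL_ACETO, "BP06": LABEL_HYDRO,
    "BP07": LABEL_HYDRO, "BP08": LABEL_HYDRO, "BP09": LABEL_BOTH,
    "BP10": LABEL_HYDRO, "BP11": LABEL_BOTH, "BP12": LABEL_HYDRO,
    "BP13": LABEL_HYDRO, "BP14": LABEL_ACETO, "BP15": LABEL_BOTH,
    "BP16": LABEL_HYDRO,
}


# ---------------------------------------------------------------------------
# factor F
# ---------------------------------------------------------------------------

def pathway_sums(profile: pd.Series, sets: KoPathwaySets | None = None) -> dict:
    """Sum a KO-indexed abundance profile over the five pathway KO groups.

    KOs absent from the profile contribute zero.  Returns a dict with keys
    ``aceto_sum, hydro_sum, methylo_sum, shared_sum, common_sum``.
    """
    sets = sets or KoPathwaySets()

    def _sum(kos):
        idx = profile.index.intersection(kos)
        return float(profile.loc[idx].sum())

    return {
        "aceto_sum": _sum(sets.acetoclastic_unique),
        "hydro_sum": _sum(sets.hydrogenotrophic_unique),
        "methylo_sum": _sum(sets.methylotrophic),
        "shared_sum": _sum(sets.shared_aceto_hydro),
        "common_sum": _sum(sets.common),
    }


def compute_F(aceto_sum: float, hydro_sum: float) -> float:
    """F = aceto_sum / hydro_sum; +inf when only acetoclastic signal, NaN when none."""
    if aceto_sum < 0 or hydro_sum < 0:
        raise ValueError("pathway abundance sums must be nonnegative")
    if hydro_sum == 0:
        return math.inf if aceto_sum > 0 else math.nan
    return aceto_sum / hydro_sum


def classify_F(F: float, lo: float = F_LOW, hi: float = F_HIGH) -> str:
    """Three-way pathway label from F; thresholds are inclusive (>= hi, <= lo)."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    if isinstance(F, float) and math.isnan(F):
        raise ValueError("no methanogenesis signal: F undefined (both sums zero)")
    if F < 0:
        raise ValueError("F must be nonnegative")
    if F >= hi:
        return LABEL_ACETO
    if F <= lo:
        return LABEL_HYDRO
    return LABEL_BOTH


@dataclass
class PathwayCall:
    """Per-unit (sample or plant) pathway call with the sums behind it."""

    unit_id: object
    aceto_sum: float
    hydro_sum: float
    methylo_sum: float
    shared_sum: float
    common_sum: float
    F: float
    label: str | None
    error: str | None = None


def classify_units(
    X_ko: pd.DataFrame,
    sets: KoPathwaySets | None = None,
    mode: str = "per_replicate",
    lo: float = F_LOW,
    hi: float = F_HIGH,
) -> list[PathwayCall]:
    """Classify every sample (``per_replicate``) or plant (``per_plant``) of a
    KO-level abundance table.

    ``per_plant`` first averages replicates within each plant (re-closed to
    100%).  Units where F is undefined carry ``label=None`` and an error
    message; remaining units are still classified.
    """
    if mode == "per_plant":
        X_ko = plant_means(X_ko)
    elif mode != "per_replicate":
        raise ValueError(f"unknown mode {mode!r}")
    sets = sets or KoPathwaySets()
    calls = []
    for unit_id, row in X_ko.iterrows():
        sums = pathway_sums(row, sets)
        F = compute_F(sums["aceto_sum"], sums["hydro_sum"])
        try:
            label, err = classify_F(F, lo=lo, hi=hi), None
        except ValueError as exc:
            label, err = None, str(exc)
        calls.append(PathwayCall(unit_id=unit_id, F=F, label=label, error=err, **sums))
    return calls


def calls_to_frame(calls: list[PathwayCall]) -> pd.DataFrame:
    """Tidy DataFrame view of a list of pathway calls."""
    return pd.DataFrame(
        [{"unit_id": c.unit_id, "aceto_sum": c.aceto_sum, "hydro_sum": c.hydro_sum,
          "methylo_sum": c.methylo_sum, "shared_sum": c.shared_sum,
          "common_sum": c.common_sum, "F": c.F, "label": c.label, "error": c.error}
         for c in calls]
    ).set_index("unit_id")


class PathwayClassifier(ClassifierMixin, BaseEstimator):
    """Factor-F methanogenic pathway classifier (scikit-learn estimator).

    ``predict(X)`` expects a KO-level abundance table (samples x KO columns)
    and returns one of ``'acetoclastic' | 'hydrogenotrophic' | 'both'`` per
    row.  ``decision_function`` returns F itself.  The estimator is
    rule-based: ``fit`` only validates parameters and records the KO sets.

    Parameters
    ----------
    lo, hi : float
        Inclusive thresholds on F (defaults 0.4 and 2.5).
    ko_sets : KoPathwaySets, optional
        Override for the packaged pathway KO sets.
    """

    def __init__(self, lo: float = F_LOW, hi: float = F_HIGH,
                 ko_sets: KoPathwaySets | None = None):
        self.lo = lo
        self.hi = hi
        self.ko_sets = ko_sets

    def fit(self, X=None, y=None):
        if not self.lo < self.hi:
            raise ValueError("require lo < hi")
        self.ko_sets_ = self.ko_sets or KoPathwaySets()
        self.classes_ = np.array([LABEL_ACETO, LABEL_BOTH, LABEL_HYDRO])
        return self

    def _calls(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self)
        calls = classify_units(X, sets=self.ko_sets_, mode="per_replicate",
                               lo=self.lo, hi=self.hi)
        return calls_to_frame(calls)

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Factor F per sample (may be +inf; NaN where undefined)."""
        return self._calls(X)["F"].to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        frame = self._calls(X)
        if frame["label"].isna().any():
            bad = frame.index[frame["label"].isna()][0]
            raise ValueError(f"no methanogenesis signal in unit {bad!r}: F undefined")
        return frame["label"].to_numpy()

    def report(self, X: pd.DataFrame) -> pd.DataFrame:
        """Full per-sample report (sums, F, label)."""
        return self._calls(X)
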