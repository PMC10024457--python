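"""Quadratic discriminant phenotype classification and its Monte-Carlo harness.

The four leaf-surface phenotypes (glossy wax, glaucous wax, hairy, glabrous)
are separated in the two-feature space (R_Qav, DIFF_R) by quadratic
discriminant analysis with equal prior probabilities: each class gets its own
Gaussian (sample mean, unbiased sample covariance) and a point is assigned to
the class with the largest Gaussian log-density (priors being equal). Equal
priors mean predictions do not follow class frequency in the training data.

The evaluation harness repeats a random 150/199 train/test split many times
(10,000 in the full protocol), refits on each training set, classifies the
held-out set, and reports the distribution of correct-classification rates
overall and per class.

Usage follows the Model -> fit() -> Results pattern::

    model = PhenotypeQDA.from_dataframe(df)      # columns R_Qav, DIFF_R, label
    res = model.fit()
    print(res.summary())
    labels = res.predict(X)
    mc = monte_carlo_evaluation(df, n_train=150, n_runs=10000, seed=17)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EvaluationError, FitError, ParameterError, SplitError

__all__ = [
    "CLASS_ORDER",
    "PhenotypeQDA",
    "QDAResults",
    "MonteCarloResult",
    "run_split",
    "monte_carlo_evaluation",
]

#: fixed label order used for tie-breaking and reporting
CLASS_ORDER = ("glossy", "glaucous", "hairy", "glabrous")

RIDGE_CONDITION_LIMIT = 1e12


def _ordered_classes(labels: np.ndarray) -> list[str]:
    present = set(str(l) for l in labels)
    ordered = [c for c in CLASS_ORDER if c in present]
    ordered += sorted(present - set(CLASS_ORDER))
    return ordered


class PhenotypeQDA:
    """Quadratic discriminant model over a labeled 2-feature table.

    Parameters
    ----------
    exog : (n, 2) array
        Feature rows, by convention (R_Qav, DIFF_R). No scaling is applied:
        QDA is equivariant to per-feature scaling through its covariances,
        so R_Qav stays on its native 1e-4 scale.
    endog : (n,) array of str
        Phenotype labels.
    priors : dict or None
        Class prior probabilities; the default is equal priors over the
        classes present, the study protocol.
    """

    def __init__(self, exog, endog, priors: dict[str, float] | None = None):
        self.exog = np.asarray(exog, dtype=float)
        self.endog = np.asarray(endog)
        if self.exog.ndim != 2 or self.exog.shape[1] != 2:
            raise ParameterError("exog must be (n, 2): R_Qav and DIFF_R")
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ParameterError("exog and endog lengths differ")
        self.classes = _ordered_classes(self.endog)
        if priors is None:
            p = 1.0 / len(self.classes)
            self.priors = {c: p for c in self.classes}
        else:
            total = sum(priors.values())
            if not np.isclose(total, 1.0):
                raise ParameterError("priors must sum to 1")
            self.priors = {c: float(priors[c]) for c in self.classes}

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        feature_cols: tuple[str, str] = ("R_Qav", "DIFF_R"),
        label_col: str = "label",
        priors: dict[str, float] | None = None,
    ) -> "PhenotypeQDA":
        missing = [c for c in (*feature_cols, label_col) if c not in data.columns]
        if missing:
            raise ParameterError(f"missing columns: {missing}")
        return cls(
            data.loc[:, list(feature_cols)].to_numpy(dtype=float),
            data[label_col].to_numpy(),
            priors=priors,
        )

    def fit(self, pooled_covariance: bool = False) -> "QDAResults":
        """Estimate per-class Gaussians (deterministic; no randomness).

        Class means are sample means and class covariances unbiased (n-1)
        sample covariances, ridge-regularized only when nearly singular.
        ``pooled_covariance=True`` replaces every class covariance with the
        pooled within-class covariance, in which limit the quadratic
        boundary degenerates to the linear-discriminant rule.
        """
        means: dict[str, np.ndarray] = {}
        covs: dict[str, np.ndarray] = {}
        counts: dict[str, int] = {}
        for c in self.classes:
            x = self.exog[self.endog == c]
            if x.shape[0] < 3:
                raise FitError(f"class {c!r} has fewer than 3 samples")
            means[c] = x.mean(axis=0)
            cov = np.cov(x, rowvar=False, ddof=1)
            counts[c] = x.shape[0]
            covs[c] = cov
        if pooled_covariance:
            dof = sum(counts[c] - 1 for c in self.classes)
            pooled = sum((counts[c] - 1) * covs[c] for c in self.classes) / dof
            covs = {c: pooled.copy() for c in self.classes}
        for c in self.classes:
            covs[c] = _regularize(covs[c], c)
        return QDAResults(
            classes=list(self.classes),
            means=means,
            covariances=covs,
            priors=dict(self.priors),
            n_per_class=counts,
            model=self,
        )


def _regularize(cov: np.ndarray, name: str) -> np.ndarray:
    """Ridge a near-singular covariance; error if it stays singular."""
    cov = np.asarray(cov, dtype=float)
    if np.linalg.cond(cov) > RIDGE_CONDITION_LIMIT or not np.all(
        np.isfinite(np.linalg.eigvalsh(cov))
    ):
        cov = cov + (1e-8 * np.trace(cov) / 2.0) * np.eye(2)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular covariance for class {name!r}") from exc
    return cov


@dataclass
class QDAResults:
    """Fitted per-class Gaussian parameters and the prediction rule."""

    classes: list[str]
    means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    priors: dict[str, float]
    n_per_class: dict[str, int] = field(default_factory=dict)
    model: PhenotypeQDA | None = None

    def __post_init__(self) -> None:
        self._precisions = {
            c: np.linalg.inv(self.covariances[c]) for c in self.classes
        }
        self._log_dets = {
            c: float(np.linalg.slogdet(self.covariances[c])[1]) for c in self.classes
        }

    @classmethod
    def from_parameters(
        cls,
        means: dict[str, np.ndarray],
        covariances: dict[str, np.ndarray],
        priors: dict[str, float] | None = None,
    ) -> "QDAResults":
        """Build a results object directly from Gaussian parameters."""
        classes = _ordered_classes(np.asarray(list(means)))
        if priors is None:
            priors = {c: 1.0 / len(classes) for c in classes}
        return cls(
            classes=classes,
            means={c: np.asarray(means[c], dtype=float) for c in classes},
            covariances={c: np.asarray(covariances[c], dtype=float) for c in classes},
            priors=priors,
        )

    def decision_scores(self, x) -> np.ndarray:
        """Per-class discriminant scores (Gaussian log-density + log prior)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if not np.all(np.isfinite(x)):
            raise ParameterError("feature vectors must be finite")
        scores = np.empty((x.shape[0], len(self.classes)))
        for j, c in enumerate(self.classes):
            d = x - self.means[c]
            maha = np.einsum("ni,ij,nj->n", d, self._precisions[c], d)
            scores[:, j] = (
                -0.5 * maha - 0.5 * self._log_dets[c] + np.log(self.priors[c])
            )
        return scores

    def predict(self, x) -> np.ndarray:
        """Most likely phenotype per row; ties resolve in CLASS_ORDER."""
        scores = self.decision_scores(x)
        idx = np.argmax(scores, axis=1)  # first max -> earliest class on ties
        return np.array([self.classes[i] for i in idx])

    def summary(self) -> str:
        lines = [
            "Quadratic Discriminant Analysis (equal priors)" if _equal(
                self.priors
            ) else "Quadratic Discriminant Analysis",
            f"features: (R_Qav, DIFF_R)   classes: {len(self.classes)}",
            "-" * 66,
            f"{'class':<10}{'n':>6}{'prior':>8}{'mean R_Qav':>14}{'mean DIFF_R':>13}"
            f"{'|cov|^1/2':>13}",
        ]
        for c in self.classes:
            m = self.means[c]
            gen_sd = float(np.sqrt(np.sqrt(np.linalg.det(self.covariances[c]))))
            n = self.n_per_class.get(c, 0)
            lines.append(
                f"{c:<10}{n:>6}{self.priors[c]:>8.3f}{m[0]:>14.3e}{m[1]:>13.3f}"
                f"{gen_sd:>13.3e}"
            )
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "classes": self.classes,
            "priors": self.priors,
            "means": {c: self.means[c].tolist() for c in self.classes},
            "covariances": {
                c: self.covariances[c].tolist() for c in self.classes
            },
            "n_per_class": self.n_per_class,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "QDAResults":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            classes=list(payload["classes"]),
            means={c: np.asarray(v) for c, v in payload["means"].items()},
            covariances={
                c: np.asarray(v) for c, v in payload["covariances"].items()
            },
            priors={c: float(v) for c, v in payload["priors"].items()},
            n_per_class={c: int(v) for c, v in payload.get("n_per_class", {}).items()},
        )

    def plot_classification_space(self, data: pd.DataFrame | None = None, ax=None):
        """Decision regions over (R_Qav, DIFF_R), optionally with sample points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        if data is not None:
            x0 = data["R_Qav"].to_numpy()
            x1 = data["DIFF_R"].to_numpy()
        else:
            x0 = np.concatenate([[m[0]] for m in self.means.values()])
            x1 = np.concatenate([[m[1]] for m in self.means.values()])
        pad0 = 0.1 * (x0.max() - x0.min() + 1e-12)
        pad1 = 0.1 * (x1.max() - x1.min() + 1e-12)
        g0 = np.linspace(x0.min() - pad0, x0.max() + pad0, 200)
        g1 = np.linspace(x1.min() - pad1, x1.max() + pad1, 200)
        gx, gy = np.meshgrid(g0, g1)
        z = self.predict(np.column_stack([gx.ravel(), gy.ravel()]))
        zi = np.array([self.classes.index(c) for c in z]).reshape(gx.shape)
        ax.contourf(gx, gy, zi, levels=len(self.classes), alpha=0.25, cmap="viridis")
        if data is not None:
            for c in self.classes:
                sel = data["label"] == c
                ax.scatter(x0[sel], x1[sel], s=12, label=c)
            ax.legend(fontsize=8)
        ax.set_xlabel("R_Qav")
        ax.set_ylabel("DIFF_R")
        ax.set_title("Leaf surface phenotype classification space")
        return ax


def _equal(priors: dict[str, float]) -> bool:
    vals = list(priors.values())
    return np.allclose(vals, vals[0])


# ---------------------------------------------------------------------------
# Monte-Carlo split evaluation
# ---------------------------------------------------------------------------


def run_split(
    labels,
    n_train: int,
    seed: int | np.random.Generator,
    require_all_classes: bool = True,
    max_retries: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random train/test partition of row indices.

    Deterministic under the seed; sizes exactly (n_train, n - n_train).
    When ``require_all_classes`` is set, a draw leaving some class absent
    from the training rows is rejected and redrawn (up to ``max_retries``).
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if not 0 < n_train < n:
        raise ParameterError("n_train must be in (0, n_samples)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    classes = set(labels.tolist())
    for _ in range(max_retries):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        if not require_all_classes or set(labels[train].tolist()) == classes:
            return np.sort(train), np.sort(test)
    raise SplitError(
        f"no split kept every class in training after {max_retries} draws"
    )


@dataclass
class MonteCarloResult:
    """Distribution of correct-classification rates over random splits."""

    classes: list[str]
    rates: np.ndarray  # (n_runs,) overall per-run rate
    class_rates: pd.DataFrame  # (n_runs, n_classes), NaN if class absent in test
    confusions: np.ndarray  # (n_runs, k, k), rows = true class
    n_train: int
    n_test: int
    seed: int
    n_skipped: int = 0

    @property
    def mean_rate(self) -> float:
        return float(self.rates.mean())

    @property
    def sd_rate(self) -> float:
        return float(self.rates.std(ddof=1)) if self.rates.size > 1 else 0.0

    @property
    def min_rate(self) -> float:
        return float(self.rates.min())

    @property
    def max_rate(self) -> float:
        return float(self.rates.max())

    def class_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.class_rates.mean(),
                "sd": self.class_rates.std(ddof=1),
                "min": self.class_rates.min(),
                "max": self.class_rates.max(),
            }
        )

    def summary(self) -> str:
        lines = [
            f"Monte-Carlo QDA evaluation: {self.rates.size} runs, "
            f"{self.n_train}/{self.n_test} train/test split",
            f"overall correct-classification rate: mean {100*self.mean_rate:.1f}%  "
            f"sd {100*self.sd_rate:.1f}%  min {100*self.min_rate:.1f}%  "
            f"max {100*self.max_rate:.1f}%",
            "-" * 60,
        ]
        cs = self.class_summary()
        for c in self.classes:
            lines.append(
                f"{c:<10} mean {100*cs.loc[c,'mean']:5.1f}%   "
                f"sd {100*cs.loc[c,'sd']:4.1f}%"
            )
        if self.n_skipped:
            lines.append(f"skipped runs: {self.n_skipped}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "classes": self.classes,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "seed": self.seed,
            "n_runs": int(self.rates.size),
            "n_skipped": self.n_skipped,
            "overall": {
                "mean": self.mean_rate,
                "sd": self.sd_rate,
                "min": self.min_rate,
                "max": self.max_rate,
            },
            "per_class": {
                c: {
                    "mean": float(self.class_rates[c].mean()),
                    "sd": float(self.class_rates[c].std(ddof=1)),
                }
                for c in self.classes
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    def per_run_frame(self) -> pd.DataFrame:
        out = self.class_rates.copy()
        out.insert(0, "overall", self.rates)
        return out

    def plot_rate_histogram(self, ax=None, bins: int = 30):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(100 * self.rates, bins=bins, color="#4c72b0")
        ax.set_xlabel("correct classification rate (%)")
        ax.set_ylabel("runs")
        return ax


def monte_carlo_evaluation(
    data: pd.DataFrame,
    n_train: int = 150,
    n_runs: int = 10_000,
    seed: int = 0,
    feature_cols: tuple[str, str] = ("R_Qav", "DIFF_R"),
    label_col: str = "label",
    max_skip_fraction: float = 0.01,
) -> MonteCarloResult:
    """Repeated random-split QDA evaluation.

    For each run a fresh uniform split is drawn from an independently
    seeded substream (master seed spawns per-run streams, so any single run
    is reproducible), the model is refit on the training rows and the test
    rows are classified. Runs whose fit fails (degenerate split) are
    skipped; more than ``max_skip_fraction`` skips aborts the evaluation.
    """
    if n_runs < 1:
        raise ParameterError("n_runs must be at least 1")
    X = data.loc[:, list(feature_cols)].to_numpy(dtype=float)
    y = data[label_col].to_numpy()
    classes = _ordered_classes(y)
    k = len(classes)
    class_index = {c: i for i, c in enumerate(classes)}

    streams = np.random.SeedSequence(seed).spawn(n_runs)
    rates = np.empty(n_runs)
    class_rates = np.full((n_runs, k), np.nan)
    confusions = np.zeros((n_runs, k, k), dtype=int)
    kept = 0
    skipped = 0
    for run, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        try:
            train, test = run_split(y, n_train, rng)
            res = PhenotypeQDA(X[train], y[train]).fit()
            pred = res.predict(X[test])
        except (FitError, SplitError):
            skipped += 1
            continue
        truth = y[test]
        conf = np.zeros((k, k), dtype=int)
        for t, p in zip(truth, pred):
            conf[class_index[t], class_index[p]] += 1
        confusions[kept] = conf
        rates[kept] = np.trace(conf) / conf.sum()
        row_tot = conf.sum(axis=1)
        with np.errstate(invalid="ignore"):
            per_class = np.where(row_tot > 0, np.diag(conf) / row_tot, np.nan)
        class_rates[kept] = per_class
        kept += 1
    if skipped > max_skip_fraction * n_runs:
        raise EvaluationError(
            f"{skipped}/{n_runs} runs skipped (degenerate splits)"
        )
    return MonteCarloResult(
        classes=classes,
        rates=rates[:kept],
        class_rates=pd.DataFrame(class_rates[:kept], columns=classes),
        confusions=confusions[:kept],
        n_train=n_train,
        n_test=int(y.shape[0] - n_train),
        seed=seed,
        n_skipped=skipped,
    )
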