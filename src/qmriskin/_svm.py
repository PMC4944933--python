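"""Thin RBF C-SVC wrapper over scikit-learn's libsvm binding.

The leave-one-out grid search performs hundreds of thousands of fits on
tiny (<= 17-sample) training sets; calling libsvm through its low-level
binding avoids per-fit estimator overhead. Predictions are identical to
``sklearn.svm.SVC`` (same solver, same defaults), which remains available
as a fallback and as the cross-check used in the tests.
"""

from __future__ import annotations

import numpy as np

try:  # private but stable binding; fall back to the public estimator
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
    _HAVE_LOWLEVEL = True
except ImportError:  # pragma: no cover
    _HAVE_LOWLEVEL = False

from sklearn.svm import SVC

__all__ = ["fit_predict_rbf", "HAVE_LOWLEVEL"]

HAVE_LOWLEVEL = _HAVE_LOWLEVEL


def fit_predict_rbf(X_train, y_train, X_test, C, gamma):
    """Train an RBF C-SVC and predict labels for ``X_test``.

    ``y_train`` is an integer 0/1 array. If the training set contains a
    single class, that class is predicted for every test point (libsvm
    cannot train on one class; this arises only in degenerate folds).
    """
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    if classes.size == 1:
        return np.full(len(X_test), classes[0])
    if _HAVE_LOWLEVEL:
        Xtr = np.ascontiguousarray(X_train, dtype=np.float64)
        Xte = np.ascontiguousarray(X_test, dtype=np.float64)
        yf = y_train.astype(np.float64)
        model = _libsvm.fit(Xtr, yf, svm_type=0, kernel="rbf",
                            C=float(C), gamma=float(gamma), tol=1e-3)
        # fit returns (support, SV, nSV, sv_coef, intercept, probA, probB,
        # fit_status, n_iter); predict wants the first seven
        pred = _libsvm.predict(Xte, *model[:7], svm_type=0, kernel="rbf",
                               gamma=float(gamma))
        return pred.astype(int)
    clf = SVC(C=C, gamma=gamma)  # pragma: no cover
    clf.fit(X_train, y_train)
    return clf.predict(X_test)
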