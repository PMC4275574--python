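"""Compare the connectivity estimators on one simulated subject.

From a single subject's cleaned time-series we compute the sample
covariance, Pearson correlation, full inverse covariance, partial
correlation, and the graphical-LASSO sparse precision along the penalty
path, scoring each penalty with the BIC.
"""

import numpy as np

import sparseconn as sc

precision, support = sc.random_sparse_precision(n_p=10, density=0.15, seed=2)
raw, _ = sc.simulate_subject(precision, n_t=400, seed=3)
ts = sc.clean_timeseries(raw)

cov = sc.sample_covariance(ts.data)
corr = sc.pearson_correlation(ts.data)
prec = sc.full_inverse_covariance(cov)
theta = sc.partial_correlation(prec)
print(f"true precision has {len(support)} off-diagonal edges")
print(f"correlation range [{corr.data.min():.2f}, "
      f"{np.sort(corr.data.ravel())[-11]:.2f}] (off-diagonal max)")

n_t = ts.data.shape[0]
print("\nlambda    nonzeros   log-lik     BIC")
for lam in (0.1, 0.01, 0.001):
    omega = sc.graphical_lasso(cov, lam)
    rec = sc.bic_score(omega, cov, n_t)
    print(f"{lam:<8}  {rec.n_nonzero:>5}    {rec.log_likelihood:9.2f}  "
          f"{rec.bic:9.1f}")

# The BIC trades fit against d = m(m-1)/2 degrees of freedom: the sparsest
# estimate that still explains the covariance wins.
best = min((sc.bic_score(sc.graphical_lasso(cov, lam), cov, n_t).bic, lam)
           for lam in (0.1, 0.01, 0.001))
print(f"\nBIC-selected lambda: {best[1]}")
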