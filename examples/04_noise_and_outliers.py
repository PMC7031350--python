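"""How multiplicative noise and outliers erode the linear verdict.

Reproduces the two robustness studies on a linear ground truth y = x:
(1) increasing the multiplicative noise amplitude α and (2) converting n of
100 points into outliers by redrawing their Gaussian noise from a 10×
flatter distribution.  Both stress the linearity stage; the printed OLS R²
shows when a linear model stops being good enough.
"""

import numpy as np
from sklearn.linear_model import LinearRegression

from partwise import SyntheticSpec, make_dataset

print("-- multiplicative noise on y = x (N=500) --")
print("alpha  OLS R2")
for alpha in (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5):
    ds = make_dataset(SyntheticSpec(kind="linear", n=500, alpha=alpha, seed=10))
    r2 = LinearRegression().fit(ds.X, ds.y).score(ds.X, ds.y)
    print(f"{alpha:5.2f}  {r2:6.3f}")

print()
print("-- outliers in y = x + N(0, 0.25) (N=100, sigma2 = 10*sigma1) --")
print("n_outliers  OLS R2  flagged-residual var / clean var")
for n_out in (0, 1, 5, 10, 15, 20, 25):
    ds = make_dataset(SyntheticSpec(kind="outliered", n=100, n_outliers=n_out, seed=3))
    r2 = LinearRegression().fit(ds.X, ds.y).score(ds.X, ds.y)
    res = ds.y - ds.meta["ground_truth"]
    mask = ds.meta["outlier_mask"]
    ratio = res[mask].var() / res[~mask].var() if n_out else float("nan")
    print(f"{n_out:10d}  {r2:6.3f}  {ratio:8.1f}")

print()
print("Low alpha / few outliers leave the linear fit essentially intact;")
print("past roughly 10-20% contamination the R2 decays and the staged")
print("pipeline would move on to non-linear models.")
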