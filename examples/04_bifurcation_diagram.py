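"""Two-parameter bifurcation skeleton of the delayed ring field.

Computes the vertical pitchfork line sigma = sigma0 (delay-independent, since
a zero eigenvalue kills the delay factor), traces the Hopf curve sigma_H(c)
(minimal gain with a purely imaginary characteristic pair), and locates the
fold-Hopf point where the two intersect.
"""
import numpy as np

from nfdelay import fold_hopf, hopf_curve, make_ring_model, pitchfork_gain

model = make_ring_model([(0, -1.0), (2, 1.5)], c=1.0, sigma=1.0, n=48)

sigma0 = pitchfork_gain(model)
print(f"pitchfork gain sigma0 = {sigma0:.6f}  (= 8/(3 pi), vertical in c)")

print("Hopf curve (minimal gain with an i*omega pair):")
for pt in hopf_curve(model, [0.5, 1.0, 2.0, 3.0, 4.0, 5.0]):
    print(f"  c={pt.c:4.1f}:  sigma_H={pt.sigma:.4f}  omega={pt.omega:.4f}  mode={pt.mode}")

fh = fold_hopf(model, (2.0, 5.0), tol_c=0.02)
print(f"fold-Hopf point: c* = {fh.c:.3f}, sigma = sigma0 = {fh.sigma:.4f}, "
      f"omega* = {fh.omega:.4f}")
print()
print("Below min(sigma0, sigma_H(c)) the trivial state is stable; crossing")
print("the pitchfork line creates stationary patterns, crossing the Hopf")
print("curve starts oscillations; at c* both happen at once.")
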