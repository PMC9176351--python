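"""The reward r(I) = F(I) * G(I) on real molecules and on a grid.

F maps the absorption-wavelength estimate through a rising tanh
centred at theta = 400 nm; G maps the synthetic-accessibility score
through a falling tanh centred at SA = 4. Both live in (0, 1), so the
product rewards molecules that are simultaneously red-shifted and
synthesizable.
"""

from cfgmon import (
    reward,
    sa_score,
    sa_term,
    surrogate_lambda,
    wavelength_term,
)
from cfgmon.catalog import make_record

print("F at the 400 nm criterion:", wavelength_term(400.0))
print("G at the SA pivot 4:      ", sa_term(4.0))
print()

print(f"{'molecule':28s} {'lambda_hat':>10s} {'SA':>5s} {'F':>6s} {'G':>6s} {'r':>6s}")
for name, smi in [
    ("methane", "C"),
    ("benzene", "c1ccccc1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("1,4-benzoquinone", "O=C1C=CC(=O)C=C1"),
    ("1,2-naphthoquinone", "O=C1C(=O)c2ccccc2C=C1"),
]:
    rec = make_record(0, smi)
    b = reward(rec)
    print(
        f"{name:28s} {b.lambda_value:>8.0f}nm {b.sa_value:>5.2f} "
        f"{b.f:>6.3f} {b.g:>6.3f} {b.r:>6.3f}"
    )
print()
print("surrogate wavelength = 150 + 25*conjugate_length + 20*aromatic_rings;")
print("more conjugation -> larger F; harder synthesis (higher SA) -> smaller G.")
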