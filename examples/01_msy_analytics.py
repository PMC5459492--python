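"""Analytics of the harvested logistic (Gordon-Schaefer) model.

Computes the equilibrium stock as a function of total effort, the effort
that maximises the sustainable yield, and the yield itself, for the default
parameter set (mu_R = 0.1/s, K = 100, q = 0.01).
"""

from cprsim import (
    SchaeferParams,
    equilibrium_resource,
    msy_effort,
    msy_yield,
    productivity_max,
    sustainable_yield,
)

params = SchaeferParams()

print(f"carrying capacity K           : {params.K}")
print(f"productivity peaks at         : {productivity_max(params)}  (= K/2)")
print(f"MSY total effort mu_R/(2q)    : {msy_effort(params)}")
print(f"maximum sustainable yield     : {msy_yield(params)}  (= mu_R*K/4, per s)")
for F in (0.0, 2.5, 5.0, 7.5, 10.0):
    print(
        f"  total effort {F:4.1f}: equilibrium stock {equilibrium_resource(params, F):6.2f}, "
        f"sustained harvest {sustainable_yield(params, F):5.3f}/s"
    )
# Above total effort mu_R/q = 10 the only equilibrium is collapse: the
# sustained harvest drops to zero even though instantaneous harvest is high.
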