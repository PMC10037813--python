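# Generic model-analysis configuration: a population of one million with
# constant size and constant services capacity.  Initial stocks and capacity
# are deliberately unset; analyses choose them per scenario.
i: 0.05496       # per-capita services engagement rate (1/year)
gamma: 0.0       # proportion severe at initial engagement
v: 0.5882        # per-capita disease progression rate (1/year)
u: 0.3096        # per-capita spontaneous recovery rate (1/year)
k: 2.0           # mean services per mild/moderate patient (services/person)
theta: 10.0      # severe-vs-mild services ratio
r: 0.4460        # proportion of treated patients who recover
mu: 0.008772     # per-capita mortality, mild/moderate (1/year)
eta: 1.3971      # mortality hazard ratio, severe
g: 0.0           # population increase (persons/year)
h: 0.0           # capacity increase (services/year per year)
M0: null
S0: null
P0: 1000000.0
C0: null
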