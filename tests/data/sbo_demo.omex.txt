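model sbo_demo
  compartment C1 = 1
  C1.sboTerm = SBO:0000290
  species E = 1, P = 0
  E.sboTerm = SBO:0000252
  P.sboTerm = SBO:0000297
  J0: E => P; kcat*E
  J0.sboTerm = SBO:0000176
  kcat = 0.2
end

m1 = model sbo_demo
sim1 = simulate uniform(0, 10, 50)
t1 = run sim1 on m1
report time, E, P
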