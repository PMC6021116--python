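model reversible_pair
  species A = 10, B = 0
  J0: A -> B; k1*(A - B)
  k1 = 1
end

m1 = model reversible_pair
sim1 = simulate uniform(0, 5, 100)
t1 = run sim1 on m1
plot "A/B relaxation" time vs A, B
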