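model decay2
  species S = 10
  J0: S => ; k1*S
  k1 = 0.5
end

m1 = model decay2 with k1 = 0.5
m2 = model decay2 with k1 = 1.5
sim1 = simulate uniform(0, 4, 100)
t1 = run sim1 on m1
t2 = run sim1 on m2
plot "two parameter sets" time vs S
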