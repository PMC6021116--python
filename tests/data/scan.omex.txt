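model decay
  species S = 10
  J0: S => ; k1*S
  k1 = 0.5
end

m1 = model decay
sim1 = simulate uniform(0, 2, 50)
t1 = run sim1 on m1
t2 = repeat t1 for k1 in uniform(0.1, 1, 5), reset=true
plot "decay scan" t2.time vs t2.S
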