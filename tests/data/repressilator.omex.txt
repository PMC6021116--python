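model repressilator
  species m1 = 10, m2 = 0, m3 = 0
  species p1 = 0, p2 = 0, p3 = 0
  J1: => m1; alpha/(1 + p3^n) + alpha0
  J2: => m2; alpha/(1 + p1^n) + alpha0
  J3: => m3; alpha/(1 + p2^n) + alpha0
  J4: m1 => ; m1
  J5: m2 => ; m2
  J6: m3 => ; m3
  J7: => p1; beta*m1
  J8: => p2; beta*m2
  J9: => p3; beta*m3
  J10: p1 => ; beta*p1
  J11: p2 => ; beta*p2
  J12: p3 => ; beta*p3
  alpha = 216
  alpha0 = 0.216
  beta = 5
  n = 2
end

mod1 = model repressilator
sim1 = simulate uniform(0, 100, 500)
t1 = run sim1 on mod1
plot "repressilator" time vs p1, p2, p3
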