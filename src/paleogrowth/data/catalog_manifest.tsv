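name	family_class	k	param_names	constraints	reconstructed	formula
Algebraic 2	attenuating	2	a,c	a > 0, c > 0	True	y = a*c*t/sqrt(1+(c*t)^2)
Arctangent 2	attenuating	2	a,c	a > 0, c > 0	True	y = a*(2/pi)*arctan(c*t)
Confined Exponential 3	attenuating	3	a,b,c	a > 0, c > 0, b <= 0 (inflection pinned left of t=0)	True	y = a*exp(-exp(-c*(t-b))), b <= 0
Error Function 2	attenuating	2	a,c	a > 0, c > 0	True	y = a*erf(c*t)
Extreme Value 2	attenuating	2	a,c	a > 0, c > 0	True	y = a*(1-exp(-exp(c*t)))
Hyperbolic Tangent 2	attenuating	2	a,c	a > 0, c > 0	True	y = a*tanh(c*t)
Michaelis Menten 2	attenuating	2	a,b	a > 0, b > 0	True	y = a*t/(b+t)
Michaelis Menten 3	attenuating	3	a,b,d	a > 0, b > 0, 0 < d < a	True	y = d + (a-d)*t/(b+t)
Monomolecular 2	attenuating	2	a,c	a > 0, c > 0	False	y = a*(1-exp(-c*t))
Monomolecular 3	attenuating	3	a,c,d	a > 0, c > 0, d < a	True	y = a - (a-d)*exp(-c*t)
Power Decay 3	attenuating	3	a,c,g	a > 0, c > 0, g > 0; domain t > -1/c	True	y = a*(1-(1+c*t)^-g)
Rational 2z	attenuating	2	a,b	a > 0, b > 0; asymptote a/b; domain t > -1/b	True	y = a*t/(1+b*t)
Reciprocal 2	attenuating	2	a,b	a > 0, b > 0; domain t > 0	True	y = a - b/t
Weibull 3a	attenuating	3	a,c,g	a > 0, c > 0, 0 < g <= 1; domain t >= 0	True	y = a*(1-exp(-(c*t)^g))
Cubic 2	increasing	2	b,c	c > 0	True	y = b + c*t^3
Cubic 2b	increasing	2	b,c	b > 0	True	y = b*(t+c)^3
Cubic 3	increasing	3	d,b,c	b > 0	True	y = d + b*(t+c)^3
Exponential 2	increasing	2	b,c	b > 0, c > 0	True	y = b*exp(c*t)
Exponential 3	increasing	3	d,b,c	b > 0, c > 0	True	y = d + b*exp(c*t)
Hyperbolic Sine 2	increasing	2	b,c	b > 0, c > 0	True	y = b*sinh(c*t)
Linear 2	increasing	2	b,c	c > 0	False	y = b + c*t
Logarithmic 2	increasing	2	b,c	b > 0, c > 0; domain t > -1/c	True	y = b*log(1+c*t)
Persistence 3a	increasing	3	d,b,c	b > 0, c > 0; domain t >= 0	True	y = d + b*t*exp(c*t)
Persistence 3b	increasing	3	b,g,c	b > 0, g > 0, c > 0; domain t >= 0	True	y = b*t^g*exp(c*t)
Power 2	increasing	2	b,c	b > 0, c > 0; domain t >= 0	True	y = b*t^c
Power 3	increasing	3	d,b,c	b > 0, c > 0; domain t >= 0	True	y = d + b*t^c
Quadratic 2	increasing	2	b,c	b >= 0, c > 0; domain t >= 0	True	y = b*t + c*t^2
Quadratic 2b	increasing	2	b,c	b > 0, c >= 0; domain t >= -c	True	y = b*(t+c)^2
Quadratic 3	increasing	3	d,b,c	b >= 0, c > 0; domain t >= 0	True	y = d + b*t + c*t^2
Algebraic 3	sigmoidal	3	a,b,c	a > 0, c > 0	True	y = a*(1+u/sqrt(1+u^2))/2, u = c*(t-b)
Algebraic 4	sigmoidal	4	a,b,c,d	a > 0, c > 0, d < a	True	y = d + (a-d)*algebraic(c*(t-b))
Arctangent 3	sigmoidal	3	a,b,c	a > 0, c > 0	True	y = a*(1/2+arctan(c*(t-b))/pi)
Arctangent 4	sigmoidal	4	a,b,c,d	a > 0, c > 0, d < a	True	y = d + (a-d)*arctan(c*(t-b))
Chapman Richards 3	sigmoidal	3	a,c,g	a > 0, c > 0, g > 1	True	y = a*(1-exp(-c*t))^g
Chapman Richards 4	sigmoidal	4	a,b,c,g	a > 0, c > 0, g > 1	True	y = a*(1-exp(-c*(t-b)))^g
Cubic Rational 2	sigmoidal	2	a,b	a > 0, b > 0; domain t >= 0	True	y = a*(t/b)^3/(1+(t/b)^3)
Cubic Rational 3	sigmoidal	3	a,b,d	a > 0, b > 0, 0 < d < a; domain t >= 0	True	y = d + (a-d)*(t/b)^3/(1+(t/b)^3)
Cubic Rational 3b	sigmoidal	3	a,b,c	a > 0, c > 0; domain t >= b	True	y = a*(t-b)^3/(c+(t-b)^3)
Error Function 3	sigmoidal	3	a,b,c	a > 0, c > 0	True	y = a*(1+erf(c*(t-b)))/2
Error Function 4	sigmoidal	4	a,b,c,d	a > 0, c > 0, d < a	True	y = d + (a-d)*erf(c*(t-b))
Extreme Value 3a	sigmoidal	3	a,b,c	a > 0, c > 0	True	y = a*(1-exp(-exp(c*(t-b))))
Extreme Value 3b	sigmoidal	3	a,b,c	a > 0, c > 0	True	y = a*exp(-exp(-c*(t-b)))
Extreme Value 4	sigmoidal	4	a,b,c,d	a > 0, c > 0, d < a	True	y = d + (a-d)*(1-exp(-exp(c*(t-b))))
Frechet 2	sigmoidal	2	a,b	a > 0, b > 0; domain t > 0	True	y = a*exp(-(b/t)^1)
Frechet 3	sigmoidal	3	a,b,g	a > 0, b > 0, g > 0; domain t > 0	True	y = a*exp(-(b/t)^g)
Frechet 4	sigmoidal	4	a,b,g,d	a > 0, b > 0, g > 0, 0 < d < a; domain t > 0	True	y = d + (a-d)*exp(-(b/t)^g)
Generalized Logistic 3	sigmoidal	3	a,c,g	a > 0, c > 0, g > 1	True	y = a/(1+exp(-c*t))^g
Generalized Logistic 4	sigmoidal	4	a,b,c,g	a > 0, c > 0, g > 0	True	y = a/(1+exp(-c*(t-b)))^g
Gompertz 3	sigmoidal	3	a,b,c	a > 0, c > 0	False	y = a*exp(-exp(-c*(t-b)))
Gompertz 3b	sigmoidal	3	a,b,c	a > 0, b > 1, c > 0	True	y = a*exp(-b*exp(-c*t))
Gompertz 3z	sigmoidal	3	a,c,d	a > 0, c > 0, 0 < d < a/e (d = y(0); interior inflection)	True	y = a*exp(log(d/a)*exp(-c*t))
Gompertz 4	sigmoidal	4	a,b,c,d	a > 0, c > 0, d < a	True	y = d + (a-d)*exp(-exp(-c*(t-b)))
Gudermannian 3	sigmoidal	3	a,b,c	a > 0, c > 0	True	y = a*(1/2+arctan(sinh(c*(t-b)))/pi)
Hyperbolic Tangent 3	sigmoidal	3	a,b,c	a > 0, c > 0	True	y = a*(1+tanh(c*(t-b)))/2
Hyperbolic Tangent 4	sigmoidal	4	a,b,c,d	a > 0, c > 0, d < a	True	y = d + (a-d)*tanh(c*(t-b))
Janoschek 4	sigmoidal	4	a,c,g,d	a > 0, c > 0, g > 1, 0 < d < a; domain t >= 0	True	y = d + (a-d)*(1-exp(-(c*t)^g))
Log Normal 3	sigmoidal	3	a,b,g	a > 0, b > 0, g > 0; domain t > 0	True	y = a*Phi(g*log(t/b))
Log Normal 4	sigmoidal	4	a,b,g,d	a > 0, b > 0, g > 0, 0 < d < a; domain t > 0	True	y = d + (a-d)*Phi(g*log(t/b))
Logistic 3	sigmoidal	3	a,b,c	a > 0, c > 0	False	y = a/(1+exp(-c*(t-b)))
Logistic 3b	sigmoidal	3	a,b,c	a > 0, b > 1, c > 0	True	y = a/(1+b*exp(-c*t))
Logistic 3z	sigmoidal	3	a,c,d	a > 0, c > 0, 0 < d < a/2 (d = y(0); interior inflection)	True	y = a/(1+(a/d-1)*exp(-c*t))
Logistic 4	sigmoidal	4	a,b,c,d	a > 0, c > 0, d < a	True	y = d + (a-d)/(1+exp(-c*(t-b)))
Morgan Mercer Flodin 3	sigmoidal	3	a,b,g	a > 0, b > 0, g > 1; domain t >= 0	True	y = a*(t/b)^g/(1+(t/b)^g)
Morgan Mercer Flodin 4a	sigmoidal	4	a,b,g,d	a > 0, b > 0, g > 1, 0 < d < a; domain t >= 0	True	y = d + (a-d)*(t/b)^g/(1+(t/b)^g)
Morgan Mercer Flodin 4b	sigmoidal	4	a,b,g,d	a > 0, b > 0, g > 1, 0 < d < a; domain t >= 0	True	y = a - (a-d)/(1+(t/b)^g)
Rational 2	sigmoidal	2	a,b	a > 0, b > 0; domain t >= 0	True	y = a*(t/b)^2/(1+(t/b)^2)
Rational 3	sigmoidal	3	a,b,d	a > 0, b > 0, 0 < d < a; domain t >= 0	True	y = d + (a-d)*(t/b)^2/(1+(t/b)^2)
Rational 3b	sigmoidal	3	a,b,c	a > 0, c > 0; domain t >= b	True	y = a*(t-b)^2/(c+(t-b)^2)
Richards 4	sigmoidal	4	a,b,c,g	a > 0, c > 0, g > 0	True	y = a*(1+g*exp(-c*(t-b)))^(-1/g)
Weibull 2	sigmoidal	2	a,c	a > 0, c > 0, ; domain t >= 0	True	y = a*(1-exp(-(c*t)^2))
Weibull 3b	sigmoidal	3	a,c,g	a > 0, c > 0, g > 1; domain t >= 0	True	y = a*(1-exp(-(c*t)^g))
Weibull 4	sigmoidal	4	a,b,c,g	a > 0, c > 0, g > 1; domain t >= b	True	y = a*(1-exp(-(c*(t-b))^g))
von Bertalanffy 2	sigmoidal	2	a,c	a > 0, c > 0	True	y = a*(1-exp(-c*t))^3
von Bertalanffy 2b	sigmoidal	2	a,c	a > 0, c > 0	True	y = a*(1-exp(-c*t))^2
von Bertalanffy 3	sigmoidal	3	a,b,c	a > 0, c > 0	False	y = a*(1-exp(-c*(t-b)))^3
von Bertalanffy 3z	sigmoidal	3	a,c,d	a > 0, c > 0, 0 < d < a/4 (interior inflection)	True	y = a*(1-(1-(d/a)^(1/3))*exp(-c*t))^3
von Bertalanffy 4	sigmoidal	4	a,b,c,d	a > 0, c > 0, 0 < d < a	True	y = d + (a-d)*(1-exp(-c*(t-b)))^3
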