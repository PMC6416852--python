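term	frequency	percentage
lack of social support	52	19.5
lonely	41	15.4
no friends	35	13.2
loneliness	29	10.9
Social withdraw	26	9.8
socially isolated	22	8.3
social isolation	9	3.4
feels isolated	8	3.0
Lonely	6	2.3
lack of social supports	6	2.3
no social support	5	1.9
Loneliness	4	1.5
Limited social support	3	1.1
feel isolated	3	1.1
no family support	3	1.1
isolation and loneliness	2	0.8
Socially withdrawn	2	0.8
socially isolating	2	0.8
Social isolation	2	0.8
Limited social support	2	0.8
limited social connection	1	0.4
Limited social network	1	0.4
lack in social support	1	0.4
loss of social network	1	0.4
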