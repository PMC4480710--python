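protein_change	transactivation_class
Q331R	functional
P47S	functional
N235S	functional
R175H	non_functional
R248W	non_functional
R248Q	non_functional
R273H	non_functional
R273C	non_functional
R282W	non_functional
G245S	non_functional
R249S	non_functional
Y220C	non_functional
V157F	non_functional
C176F	non_functional
H179R	non_functional
M237I	non_functional
C242F	non_functional
G266E	non_functional
R280K	non_functional
E285K	non_functional
C135Y	non_functional
A161T	non_functional
V173L	non_functional
Y234C	non_functional
I195T	non_functional
P151S	non_functional
L194R	non_functional
Y163C	non_functional
S241F	non_functional
C238Y	non_functional
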