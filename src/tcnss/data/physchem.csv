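residue,polarity,charge,weight,hydropathy
A,nonpolar,0,89.09,1.8
C,nonpolar,0,121.16,2.5
D,negative,-1,133.10,-3.5
E,negative,-1,147.13,-3.5
F,nonpolar,0,165.19,2.8
G,nonpolar,0,75.07,-0.4
H,positive,0,155.15,-3.2
I,nonpolar,0,131.17,4.5
K,positive,1,146.19,-3.9
L,nonpolar,0,131.17,3.8
M,nonpolar,0,149.21,1.9
N,polar,0,132.12,-3.5
P,nonpolar,0,115.13,-1.6
Q,polar,0,146.15,-3.5
R,positive,1,174.20,-4.5
S,polar,0,105.09,-0.8
T,polar,0,119.12,-0.7
V,nonpolar,0,117.15,4.2
W,nonpolar,0,204.23,-0.9
Y,polar,0,181.19,-1.3
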