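operator,axis,reference_angle,repetition,measured_angle
1,X,15,1,15.30
1,X,15,2,14.99
1,X,15,3,15.23
2,X,15,1,15.18
2,X,15,2,15.22
2,X,15,3,15.00
3,X,15,1,14.97
3,X,15,2,15.20
3,X,15,3,15.01
4,X,15,1,15.00
4,X,15,2,15.02
4,X,15,3,15.01
1,Y,15,1,14.98
1,Y,15,2,15.07
1,Y,15,3,14.95
2,Y,15,1,15.30
2,Y,15,2,15.20
2,Y,15,3,15.15
3,Y,15,1,15.02
3,Y,15,2,15.15
3,Y,15,3,14.97
4,Y,15,1,15.30
4,Y,15,2,15.01
4,Y,15,3,14.98
1,Z,15,1,15.06
1,Z,15,2,15.15
1,Z,15,3,14.97
2,Z,15,1,15.21
2,Z,15,2,15.11
2,Z,15,3,14.98
3,Z,15,1,15.00
3,Z,15,2,15.00
3,Z,15,3,15.00
4,Z,15,1,14.96
4,Z,15,2,15.01
4,Z,15,3,15.02
1,X,45,1,45.01
1,X,45,2,44.90
1,X,45,3,45.03
2,X,45,1,45.01
2,X,45,2,45.10
2,X,45,3,44.98
3,X,45,1,45.06
3,X,45,2,45.03
3,X,45,3,45.00
4,X,45,1,45.10
4,X,45,2,44.97
4,X,45,3,45.01
1,Y,45,1,44.99
1,Y,45,2,45.10
1,Y,45,3,45.10
2,Y,45,1,45.00
2,Y,45,2,49.80
2,Y,45,3,45.02
3,Y,45,1,45.00
3,Y,45,2,45.01
3,Y,45,3,45.10
4,Y,45,1,45.01
4,Y,45,2,45.50
4,Y,45,3,45.00
1,Z,45,1,44.98
1,Z,45,2,45.07
1,Z,45,3,45.03
2,Z,45,1,44.95
2,Z,45,2,45.00
2,Z,45,3,44.90
3,Z,45,1,45.10
3,Z,45,2,45.20
3,Z,45,3,45.10
4,Z,45,1,45.00
4,Z,45,2,44.99
4,Z,45,3,45.10
1,X,60,1,59.78
1,X,60,2,60.10
1,X,60,3,60.50
2,X,60,1,59.98
2,X,60,2,60.00
2,X,60,3,60.01
3,X,60,1,60.10
3,X,60,2,60.11
3,X,60,3,60.11
4,X,60,1,59.88
4,X,60,2,60.40
4,X,60,3,60.01
1,Y,60,1,60.10
1,Y,60,2,59.97
1,Y,60,3,60.12
2,Y,60,1,60.20
2,Y,60,2,60.09
2,Y,60,3,59.98
3,Y,60,1,59.99
3,Y,60,2,60.01
3,Y,60,3,60.11
4,Y,60,1,60.09
4,Y,60,2,60.20
4,Y,60,3,60.02
1,Z,60,1,59.97
1,Z,60,2,60.07
1,Z,60,3,60.34
2,Z,60,1,60.15
2,Z,60,2,60.00
2,Z,60,3,60.10
3,Z,60,1,60.10
3,Z,60,2,59.96
3,Z,60,3,60.01
4,Z,60,1,60.01
4,Z,60,2,60.02
4,Z,60,3,60.15
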