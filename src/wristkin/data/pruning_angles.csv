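operator,sequence,cut,axis,angle_deg
1,1,1,X,0.56
1,1,1,Y,46.40
1,1,1,Z,45.11
1,1,2,X,0.45
1,1,2,Y,0.00
1,1,2,Z,10.11
1,1,3,X,0.10
1,1,3,Y,15.33
1,1,3,Z,47.00
1,1,4,X,2.11
1,1,4,Y,33.00
1,1,4,Z,47.33
1,1,5,X,29.22
1,1,5,Y,37.15
1,1,5,Z,15.29
1,1,6,X,1.12
1,1,6,Y,47.40
1,1,6,Z,47.33
1,1,7,X,10.13
1,1,7,Y,45.88
1,1,7,Z,45.80
1,2,1,X,15.21
1,2,1,Y,50.16
1,2,1,Z,10.61
1,2,2,X,10.37
1,2,2,Y,3.00
1,2,2,Z,23.15
1,2,3,X,15.89
1,2,3,Y,23.44
1,2,3,Z,10.70
1,2,4,X,3.10
1,2,4,Y,45.60
1,2,4,Z,39.00
1,2,5,X,13.00
1,2,5,Y,44.34
1,2,5,Z,13.34
1,2,6,X,0.25
1,2,6,Y,46.40
1,2,6,Z,46.13
1,2,7,X,0.85
1,2,7,Y,55.00
1,2,7,Z,5.11
1,3,1,X,22.23
1,3,1,Y,31.24
1,3,1,Z,27.85
1,3,2,X,0.47
1,3,2,Y,14.00
1,3,2,Z,15.30
1,3,3,X,49.00
1,3,3,Y,33.18
1,3,3,Z,11.23
1,3,4,X,0.66
1,3,4,Y,59.10
1,3,4,Z,11.14
1,3,5,X,9.05
1,3,5,Y,27.30
1,3,5,Z,4.22
1,3,6,X,22.30
1,3,6,Y,45.70
1,3,6,Z,46.00
1,3,7,X,2.76
1,3,7,Y,48.70
1,3,7,Z,47.40
2,1,1,X,18.47
2,1,1,Y,49.00
2,1,1,Z,30.16
2,1,2,X,11.21
2,1,2,Y,47.11
2,1,2,Z,20.10
2,1,3,X,45.71
2,1,3,Y,47.18
2,1,3,Z,48.55
2,1,4,X,22.12
2,1,4,Y,47.00
2,1,4,Z,15.56
2,1,5,X,0.15
2,1,5,Y,47.40
2,1,5,Z,9.56
2,1,6,X,12.88
2,1,6,Y,49.50
2,1,6,Z,9.34
2,1,7,X,11.50
2,1,7,Y,53.20
2,1,7,Z,55.80
2,2,1,X,39.45
2,2,1,Y,60.11
2,2,1,Z,15.84
2,2,2,X,0.55
2,2,2,Y,46.00
2,2,2,Z,22.17
2,2,3,X,48.34
2,2,3,Y,49.55
2,2,3,Z,49.74
2,2,4,X,33.10
2,2,4,Y,48.50
2,2,4,Z,47.88
2,2,5,X,12.44
2,2,5,Y,35.21
2,2,5,Z,45.70
2,2,6,X,2.99
2,2,6,Y,47.80
2,2,6,Z,48.01
2,2,7,X,0.00
2,2,7,Y,30.00
2,2,7,Z,10.20
2,3,1,X,39.28
2,3,1,Y,55.27
2,3,1,Z,22.26
2,3,2,X,33.24
2,3,2,Y,47.34
2,3,2,Z,10.21
2,3,3,X,44.16
2,3,3,Y,33.25
2,3,3,Z,50.22
2,3,4,X,13.44
2,3,4,Y,45.50
2,3,4,Z,50.10
2,3,5,X,22.16
2,3,5,Y,35.30
2,3,5,Z,36.00
2,3,6,X,34.78
2,3,6,Y,23.45
2,3,6,Z,12.00
2,3,7,X,11.56
2,3,7,Y,47.40
2,3,7,Z,10.66
3,1,1,X,48.08
3,1,1,Y,49.88
3,1,1,Z,3.71
3,1,2,X,23.26
3,1,2,Y,46.23
3,1,2,Z,10.33
3,1,3,X,35.28
3,1,3,Y,36.88
3,1,3,Z,55.00
3,1,4,X,10.24
3,1,4,Y,50.00
3,1,4,Z,49.33
3,1,5,X,0.22
3,1,5,Y,55.00
3,1,5,Z,50.10
3,1,6,X,24.50
3,1,6,Y,31.00
3,1,6,Z,54.20
3,1,7,X,2.61
3,1,7,Y,48.00
3,1,7,Z,10.15
3,2,1,X,46.11
3,2,1,Y,47.90
3,2,1,Z,10.28
3,2,2,X,23.64
3,2,2,Y,47.11
3,2,2,Z,8.45
3,2,3,X,45.36
3,2,3,Y,47.10
3,2,3,Z,60.00
3,2,4,X,23.22
3,2,4,Y,48.30
3,2,4,Z,45.60
3,2,5,X,11.33
3,2,5,Y,48.30
3,2,5,Z,46.80
3,2,6,X,20.68
3,2,6,Y,25.60
3,2,6,Z,45.80
3,2,7,X,10.33
3,2,7,Y,39.13
3,2,7,Z,15.28
3,3,1,X,2.13
3,3,1,Y,19.20
3,3,1,Z,14.65
3,3,2,X,48.16
3,3,2,Y,50.11
3,3,2,Z,20.70
3,3,3,X,3.70
3,3,3,Y,50.02
3,3,3,Z,15.20
3,3,4,X,32.44
3,3,4,Y,47.40
3,3,4,Z,47.60
3,3,5,X,25.50
3,3,5,Y,55.00
3,3,5,Z,47.00
3,3,6,X,23.44
3,3,6,Y,43.00
3,3,6,Z,47.40
3,3,7,X,10.45
3,3,7,Y,55.22
3,3,7,Z,49.00
4,1,1,X,0.18
4,1,1,Y,33.16
4,1,1,Z,47.80
4,1,2,X,23.45
4,1,2,Y,33.07
4,1,2,Z,25.50
4,1,3,X,4.87
4,1,3,Y,33.00
4,1,3,Z,49.70
4,1,4,X,47.70
4,1,4,Y,9.00
4,1,4,Z,48.50
4,1,5,X,12.56
4,1,5,Y,47.33
4,1,5,Z,45.80
4,1,6,X,13.21
4,1,6,Y,33.30
4,1,6,Z,49.40
4,1,7,X,3.43
4,1,7,Y,5.23
4,1,7,Z,47.88
4,2,1,X,0.23
4,2,1,Y,2.50
4,2,1,Z,46.00
4,2,2,X,22.43
4,2,2,Y,33.08
4,2,2,Z,30.80
4,2,3,X,17.50
4,2,3,Y,48.80
4,2,3,Z,34.17
4,2,4,X,12.34
4,2,4,Y,47.40
4,2,4,Z,48.45
4,2,5,X,9.21
4,2,5,Y,38.11
4,2,5,Z,46.32
4,2,6,X,2.33
4,2,6,Y,51.00
4,2,6,Z,46.88
4,2,7,X,4.15
4,2,7,Y,20.13
4,2,7,Z,45.15
4,3,1,X,0.15
4,3,1,Y,45.70
4,3,1,Z,47.84
4,3,2,X,49.58
4,3,2,Y,44.01
4,3,2,Z,48.90
4,3,3,X,23.34
4,3,3,Y,45.80
4,3,3,Z,46.11
4,3,4,X,33.60
4,3,4,Y,45.00
4,3,4,Z,49.00
4,3,5,X,20.05
4,3,5,Y,30.44
4,3,5,Z,38.00
4,3,6,X,23.44
4,3,6,Y,49.60
4,3,6,Z,48.00
4,3,7,X,33.18
4,3,7,Y,22.03
4,3,7,Z,23.08
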