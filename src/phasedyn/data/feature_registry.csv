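name,family,order
IntegratedIntensity,intensity,0
MeanIntensity,intensity,1
StdIntensity,intensity,2
MinIntensity,intensity,3
MaxIntensity,intensity,4
IntegratedIntensityEdge,intensity,5
MeanIntensityEdge,intensity,6
StdIntensityEdge,intensity,7
MinIntensityEdge,intensity,8
MaxIntensityEdge,intensity,9
MassDisplacement,intensity,10
LowerQuartileIntensity,intensity,11
MedianIntensity,intensity,12
MADIntensity,intensity,13
UpperQuartileIntensity,intensity,14
CenterMassRow,intensity,15
CenterMassCol,intensity,16
Area,shape,17
Perimeter,shape,18
FormFactor,shape,19
Compactness,shape,20
Eccentricity,shape,21
MajorAxisLength,shape,22
MinorAxisLength,shape,23
Orientation,shape,24
Solidity,shape,25
Extent,shape,26
EulerNumber,shape,27
EquivalentDiameter,shape,28
MaxFeretDiameter,shape,29
MinFeretDiameter,shape,30
MeanRadius,shape,31
MedianRadius,shape,32
MaximumRadius,shape,33
NumberOfNeighbors,neighbors,34
PercentTouching,neighbors,35
FirstClosestObjectNumber,neighbors,36
FirstClosestDistance,neighbors,37
SecondClosestObjectNumber,neighbors,38
SecondClosestDistance,neighbors,39
AngleBetweenNeighbors,neighbors,40
FracAtD_1,radial,41
FracAtD_2,radial,42
FracAtD_3,radial,43
FracAtD_4,radial,44
MeanFrac_1,radial,45
MeanFrac_2,radial,46
MeanFrac_3,radial,47
MeanFrac_4,radial,48
RadialCV_1,radial,49
RadialCV_2,radial,50
RadialCV_3,radial,51
RadialCV_4,radial,52
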